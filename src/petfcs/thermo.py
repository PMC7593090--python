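"""Eyring transition-state analysis of fitted rate constants.

A first-order rate constant k maps to a transition-state free-energy
barrier through the Eyring equation

    k = (k_B T / h) * kappa * exp(-dG / (R T)),

inverted as dG = -R T ln(k h / (kappa k_B T)).  The default physical
constants are the truncated printed values commonly used alongside this
analysis (R = 8.3145 J mol^-1 K^-1, k_B = 1.38e-23 J K^-1,
h = 6.6e-34 J s) at T = 295 K with transmission coefficient kappa = 1;
CODATA values are available via ``constants="codata"`` (the prefactor
differs by ~0.8%, the barrier by ~0.05 kJ/mol).  Standard errors on rates
are propagated to barriers by the first-order delta method,
sigma_dG = R T sigma_k / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

R_GAS = 8.3145  # J mol^-1 K^-1

_CONSTANT_SETS = {
    # (k_B [J/K], h [J s])
    "printed": (1.38e-23, 6.6e-34),
    "codata": (1.380649e-23, 6.62607015e-34),
}

DEFAULT_T = 295.0  # K


@dataclass
class EnergyBarrier:
    """An Eyring barrier with its provenance."""

    dG: float  # J mol^-1
    rate: float  # s^-1
    se_rate: float | None
    T: float
    kappa: float
    constants: str = "printed"

    @property
    def dG_kJmol(self) -> float:
        return self.dG / 1e3

    @property
    def se_dG(self) -> float | None:
        """Delta-method SE of the barrier (J mol^-1), if se_rate is known."""
        if self.se_rate is None:
            return None
        return R_GAS * self.T * self.se_rate / self.rate


def _prefactor(T: float, kappa: float, constants: str) -> float:
    kB, h = _CONSTANT_SETS[constants]
    return kB * T / h * kappa


def eyring_barrier_from_rate(
    k: float,
    T: float = DEFAULT_T,
    kappa: float = 1.0,
    se_k: float | None = None,
    constants: str = "printed",
) -> EnergyBarrier:
    """Barrier dG (J mol^-1) implied by a rate constant k (s^-1)."""
    if k <= 0 or T <= 0 or kappa <= 0:
        raise ValueError("require k > 0, T > 0, kappa > 0")
    dG = -R_GAS * T * math.log(k / _prefactor(T, kappa, constants))
    return EnergyBarrier(dG=dG, rate=k, se_rate=se_k, T=T, kappa=kappa, constants=constants)


def eyring_rate_from_barrier(
    dG: float,
    T: float = DEFAULT_T,
    kappa: float = 1.0,
    constants: str = "printed",
) -> float:
    """Rate constant (s^-1) implied by a barrier dG (J mol^-1)."""
    if T <= 0 or kappa <= 0:
        raise ValueError("require T > 0 and kappa > 0")
    return _prefactor(T, kappa, constants) * math.exp(-dG / (R_GAS * T))


def barrier_table_with_errors(
    fit,
    rate_names: tuple[str, ...] = ("k_CD", "k_DC"),
    T: float = DEFAULT_T,
    kappa: float = 1.0,
    constants: str = "printed",
) -> pd.DataFrame:
    """Per-construct Eyring barriers for the selected exchange rates.

    ``fit`` is a :class:`petfcs.globalfit.FitResult` (anything exposing a
    ``rates_table()`` DataFrame with columns construct/rate/value/se).
    Both exchange directions are emitted and labelled explicitly; rows
    with missing SE carry NaN in ``se_dG_kJmol`` rather than failing.
    """
    table = fit.rates_table() if hasattr(fit, "rates_table") else fit
    rows = []
    for _, r in table.iterrows():
        if r["rate"] not in rate_names:
            continue
        se = r.get("se")
        se = None if se is None or not np.isfinite(se) else float(se)
        b = eyring_barrier_from_rate(
            float(r["value"]), T=T, kappa=kappa, se_k=se, constants=constants
        )
        direction = {"k_CD": "C->D", "k_DC": "D->C"}.get(r["rate"], r["rate"])
        rows.append(
            {
                "construct": r["construct"],
                "direction": direction,
                "k": b.rate,
                "se_k": b.se_rate if b.se_rate is not None else np.nan,
                "dG_kJmol": b.dG_kJmol,
                "se_dG_kJmol": (b.se_dG / 1e3) if b.se_dG is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_barrier_diagram(table: pd.DataFrame, ax=None):
    """Relative barrier diagram: dG per construct for both directions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for direction, sub in table.groupby("direction"):
        ax.errorbar(
            sub["construct"],
            sub["dG_kJmol"],
            yerr=sub["se_dG_kJmol"],
            marker="o",
            linestyle="-",
            label=direction,
        )
    ax.set_ylabel(r"$\Delta G^{\ddag}$ (kJ mol$^{-1}$)")
    ax.legend()
    return ax
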