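"""Empirical autocorrelation-curve handling: load, average, fit, strip.

The measured fluorescence autocorrelation of a labelled ribosome–nascent-
chain complex is multiphasic: a ms-scale diffusion term, a ~tens-of-µs
triplet-state term, and µs-scale relaxations from PET quenching dynamics.
The empirical model fitted here is a 2D single-species diffusion law with
two exponential relaxations and one triplet term,

    G(tau) = (1 + c1 e^{-k1 tau} + c2 e^{-k2 tau})
             * (1 - F + F e^{-kf tau}) / (1 - F)
             * (1/N) * (1 + kd tau)^{-1}

with amplitudes c1, c2, apparent relaxation rates k1, k2 (s^-1), mean
molecule number N, triplet fraction F and rate kf, and inverse diffusion
time kd.  The baseline-0 ("G - 1") convention is used throughout; an
optional additive offset (frozen at 0 by default) absorbs alternative
normalizations of published tables.

Fitted envelope parameters are then used to divide the diffusion and
triplet factors out of each curve, leaving the pure dynamic component
y(tau) = c1 e^{-k1 tau} + c2 e^{-k2 tau} that the kinetic-network models
are fitted against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.stats import qmc


class FormatError(ValueError):
    """Malformed input table."""


#: canonical column names; a dialect maps these to the file's own headers
STANDARD_COLUMNS = (
    "lag_s",
    "g",
    "sd",
    "curve_id",
    "construct",
    "trp",
    "trp_mM",
    "condition",
    "replicate",
)


@dataclass
class ACFCurve:
    """One measured or simulated autocorrelation curve."""

    lags: np.ndarray
    amplitudes: np.ndarray
    sd: np.ndarray | None = None
    construct: str = ""
    trp_present: bool = True
    trp_mM: float = 0.0
    condition: str = ""
    replicate: str = "0"
    curve_id: str = ""
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.amplitudes.shape:
            raise ValueError("lags and amplitudes must be 1-D and equal length")
        if np.any(self.lags <= 0):
            bad = int(np.argmax(self.lags <= 0))
            raise ValueError(f"non-positive lag at index {bad}")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.lags.shape:
                raise ValueError("sd must match lags")
            if np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class EmpiricalParams:
    """Parameters of the empirical ACF model (all rates s^-1)."""

    c1: float
    k1: float
    c2: float
    k2: float
    N: float
    F: float
    kf: float
    kd: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.kf, self.kd) < 0:
            raise ValueError("rates must be nonnegative")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not (0 <= self.F < 1):
            raise ValueError("F must lie in [0, 1)")

    def canonical(self) -> "EmpiricalParams":
        """Return with the (c, k) pairs ordered so that k1 >= k2."""
        if self.k1 >= self.k2:
            return self
        return dataclasses.replace(self, c1=self.c2, k1=self.k2, c2=self.c1, k2=self.k1)


@dataclass
class DynamicDecay:
    """Dynamic ACF component after removing diffusion and triplet factors."""

    lags: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    source_params: EmpiricalParams | None = None
    construct: str = ""
    trp_present: bool = True
    trp_mM: float = 0.0
    curve_id: str = ""


@dataclass
class FitDiagnostics:
    ssr: float
    chi2: float
    chi2_dof: float
    n_points: int
    n_free: int
    success: bool
    n_starts: int
    message: str = ""


class FitFailure(RuntimeError):
    """Optimization did not converge; carries the best attempt."""

    def __init__(self, message: str, params: EmpiricalParams, diagnostics: FitDiagnostics):
        super().__init__(message)
        self.params = params
        self.diagnostics = diagnostics


def eval_empirical_acf(params: EmpiricalParams, lags: np.ndarray) -> np.ndarray:
    """Evaluate the empirical ACF model G(tau) on a lag grid."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be nonnegative")
    if params.F >= 1 or params.N <= 0:
        raise ValueError("require F < 1 and N > 0")
    dyn = 1.0 + params.c1 * np.exp(-params.k1 * tau) + params.c2 * np.exp(-params.k2 * tau)
    trip = (1.0 - params.F + params.F * np.exp(-params.kf * tau)) / (1.0 - params.F)
    diff = 1.0 / (params.N * (1.0 + params.kd * tau))
    return dyn * trip * diff + params.offset


def strip_static_components(
    curve: ACFCurve,
    params: EmpiricalParams,
    lag_window: tuple[float, float] | None = None,
    envelope_floor: float = 1e-3,
) -> DynamicDecay:
    """Divide the fitted diffusion and triplet factors out of a curve.

    Returns y(tau) = G(tau) N (1 + kd tau) (1 - F) /
    (1 - F + F e^{-kf tau}) - 1, which equals the pure two-exponential
    component for a curve that exactly obeys the empirical model.  Lags
    where the diffusion+triplet envelope has decayed below
    ``envelope_floor`` of its tau=0 value are dropped (dividing by a
    vanishing envelope only amplifies noise); an explicit ``lag_window``
    truncates further.
    """
    if params.F >= 1:
        raise ValueError("require F < 1")
    tau = curve.lags
    trip = (1.0 - params.F + params.F * np.exp(-params.kf * tau)) / (1.0 - params.F)
    envelope = trip / (params.N * (1.0 + params.kd * tau))
    keep = envelope >= envelope_floor * envelope[0] if len(tau) else np.array([], bool)
    if lag_window is not None:
        keep &= (tau >= lag_window[0]) & (tau <= lag_window[1])
    g = curve.amplitudes - params.offset
    y = g / envelope - 1.0
    sd = None if curve.sd is None else curve.sd / envelope
    return DynamicDecay(
        lags=tau[keep],
        values=y[keep],
        sd=None if sd is None else sd[keep],
        source_params=params,
        construct=curve.construct,
        trp_present=curve.trp_present,
        trp_mM=curve.trp_mM,
        curve_id=curve.curve_id,
    )


def average_replicates(curves: list[ACFCurve]) -> ACFCurve:
    """Pointwise mean over technical replicates sharing one lag grid.

    The per-lag standard deviation across replicates is stored in ``sd``
    (zeros for a single replicate).
    """
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(ref) or not np.allclose(c.lags, ref, rtol=1e-9, atol=0):
            raise ValueError("replicates do not share a lag grid")
    stack = np.vstack([c.amplitudes for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    first = curves[0]
    return ACFCurve(
        lags=ref.copy(),
        amplitudes=mean,
        sd=sd,
        construct=first.construct,
        trp_present=first.trp_present,
        trp_mM=first.trp_mM,
        condition=first.condition,
        replicate="mean",
        curve_id=first.curve_id or first.construct,
        n_replicates=len(curves),
    )


# ---------------------------------------------------------------------------
# fitting


_LOG_NAMES = ("c1", "k1", "c2", "k2", "N", "kf", "kd")  # log10-transformed
_DEFAULT_LOG_BOUNDS = {
    "c1": (-4, 2),
    "c2": (-4, 2),
    "k1": (3, 9),
    "k2": (2, 8),
    "N": (-3, 3),
    "kf": (2, 7),
    "kd": (-1, 6),
}


def _pack(params: EmpiricalParams, free: list[str]) -> np.ndarray:
    x = []
    for name in free:
        v = getattr(params, name)
        if name == "F":
            v = np.clip(v, 1e-6, 1 - 1e-6)
            x.append(np.log(v / (1 - v)))  # logit
        else:
            x.append(np.log10(max(v, 1e-300)))
    return np.asarray(x)


def _unpack(x: np.ndarray, free: list[str], frozen: EmpiricalParams) -> EmpiricalParams:
    kw = dataclasses.asdict(frozen)
    for name, v in zip(free, x):
        v = float(np.clip(v, -300.0, 300.0))
        kw[name] = 1.0 / (1.0 + np.exp(-v)) if name == "F" else 10.0**v
    return EmpiricalParams(**kw)


def _auto_init(curve: ACFCurve) -> EmpiricalParams:
    """Heuristic starting point from curve magnitudes."""
    g0 = max(float(curve.amplitudes[0]), 1e-3)
    # crude split: assume one molecule-scale amplitude, mid-grid rates
    lag_lo, lag_hi = curve.lags[0], curve.lags[-1]
    return EmpiricalParams(
        c1=0.5,
        k1=1.0 / (lag_lo * 30),
        c2=0.2,
        k2=1.0 / np.sqrt(lag_lo * lag_hi),
        N=max(1.0 / g0, 1e-2),
        F=0.15,
        kf=2.5e4,
        kd=3.0 / lag_hi,
    )


def fit_empirical_acf(
    curve: ACFCurve,
    init: EmpiricalParams | None = None,
    fix: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 16,
    seed: int = 0,
    weights: str = "auto",
) -> tuple[EmpiricalParams, FitDiagnostics]:
    """Weighted least-squares fit of the empirical ACF model.

    Rates, amplitudes and N are optimized in log10 space and the triplet
    fraction F in logit space, which enforces positivity and F in (0, 1)
    without explicit constraints.  A Latin-hypercube multi-start
    (``n_starts`` draws around the initial guess, seeded) guards against
    local minima; ties are broken by lowest residual, then lowest k1.
    Parameters named in ``fix`` are frozen at the given values (e.g.
    ``{"c2": 0}`` for single-exponential curves); ``bounds`` boxes
    individual parameters in natural units, the standard use being to
    keep the triplet term in its physical tens-of-µs range (e.g.
    ``{"kf": (1e4, 1e5), "F": (0.0, 0.5)}``) so it cannot absorb µs-scale
    PET relaxations — the two are otherwise the same functional form.

    Weights are 1/sd when the curve carries per-lag standard deviations
    (``weights="auto"``), else uniform (``weights="uniform"``).
    """
    fix = dict(fix or {})
    bounds = dict(bounds or {})
    all_names = ["c1", "k1", "c2", "k2", "N", "F", "kf", "kd"]
    free = [n for n in all_names if n not in fix]
    if len(curve) < len(free) + 1:
        raise ValueError(
            f"under-determined fit: {len(curve)} points for {len(free)} free parameters"
        )
    base = init if init is not None else _auto_init(curve)
    base = dataclasses.replace(base, **fix)

    if weights == "auto" and curve.sd is not None and np.all(curve.sd > 0):
        w = 1.0 / curve.sd
    else:
        w = np.ones_like(curve.lags)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x, free, base)
        return (eval_empirical_acf(p, curve.lags) - curve.amplitudes) * w

    x0 = _pack(base, free)
    starts = [x0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        unit = sampler.random(n_starts - 1)
        for row in unit:
            x = x0.copy()
            for j, name in enumerate(free):
                if name == "F":
                    f = 0.02 + 0.6 * row[j]
                    x[j] = np.log(f / (1 - f))
                else:
                    lo, hi = _DEFAULT_LOG_BOUNDS[name]
                    # sample within +-1.5 decades of the guess, clipped to bounds
                    x[j] = np.clip(x0[j] + 3.0 * (row[j] - 0.5), lo, hi)
            starts.append(x)

    lb = np.full(len(free), -np.inf)
    ub = np.full(len(free), np.inf)
    for j, name in enumerate(free):
        if name in bounds:
            lo, hi = bounds[name]
            if name == "F":
                lo = np.clip(lo, 1e-9, 1 - 1e-9)
                hi = np.clip(hi, 1e-9, 1 - 1e-9)
                lb[j], ub[j] = np.log(lo / (1 - lo)), np.log(hi / (1 - hi))
            else:
                lb[j], ub[j] = np.log10(max(lo, 1e-300)), np.log10(hi)
    bounded = np.any(np.isfinite(lb)) or np.any(np.isfinite(ub))

    best = None
    for x_start in starts:
        try:
            sol = scipy.optimize.least_squares(
                residuals,
                np.clip(x_start, lb, ub),
                method="trf" if bounded else "lm",
                bounds=(lb, ub) if bounded else (-np.inf, np.inf),
                max_nfev=4000,
            )
        except Exception:
            continue
        cand = (sol.cost * 2.0, _unpack(sol.x, free, base), sol)
        if best is None or cand[0] < best[0] - 1e-30 or (
            abs(cand[0] - best[0]) <= 1e-12 * max(cand[0], 1e-300)
            and cand[1].canonical().k1 < best[1].canonical().k1
        ):
            best = cand
    if best is None:
        raise FitFailure(
            "no start converged",
            base,
            FitDiagnostics(np.inf, np.inf, np.inf, len(curve), len(free), False, len(starts)),
        )
    ssr_w, params, sol = best
    params = params.canonical()
    resid = residuals(_pack(params, free))
    chi2 = float(resid @ resid)
    dof = len(curve) - len(free)
    diag = FitDiagnostics(
        ssr=float(np.sum((resid / w) ** 2)),
        chi2=chi2,
        chi2_dof=chi2 / dof if dof > 0 else np.inf,
        n_points=len(curve),
        n_free=len(free),
        success=bool(sol.success),
        n_starts=len(starts),
        message=str(sol.message),
    )
    return params, diag


def fit_empirical_global(
    curves: list[ACFCurve],
    share: tuple[str, ...] = ("N", "F", "kf", "kd"),
    bounds: dict[str, tuple[float, float]] | None = None,
    init: EmpiricalParams | None = None,
    n_starts: int = 8,
    seed: int = 0,
    weights: str = "auto",
) -> tuple[list[EmpiricalParams], FitDiagnostics]:
    """Simultaneous empirical fit of several curves with a shared envelope.

    The diffusion, triplet and molecule-number parameters named in
    ``share`` are estimated once for the whole set (one fluorophore, one
    complex, one focus), while each curve keeps its own relaxation
    amplitudes and rates.  Because the kinetic relaxations differ between
    curves (e.g. a construct with and without its internal Trp) but the
    photophysical envelope does not, sharing resolves the
    triplet-vs-slow-relaxation degeneracy that defeats per-curve fits.

    Returns one parameter set per curve (shared entries identical) and
    pooled diagnostics.
    """
    if not curves:
        raise ValueError("no curves")
    per_curve = [n for n in ("c1", "k1", "c2", "k2", "N", "F", "kf", "kd") if n not in share]
    bounds = dict(bounds or {})

    # seed the shared envelope from individual fits
    singles = []
    for i, c in enumerate(curves):
        p, _ = fit_empirical_acf(c, init=init, bounds=bounds, n_starts=n_starts,
                                 seed=seed + i, weights=weights)
        singles.append(p)

    import lmfit

    params = lmfit.Parameters()

    def add(name, value, key):
        if key == "F":
            v = float(np.clip(value, 1e-6, 1 - 1e-6))
            lo, hi = bounds.get("F", (1e-9, 1 - 1e-9))
            params.add(name, value=np.log(v / (1 - v)),
                       min=np.log(lo / (1 - lo)), max=np.log(hi / (1 - hi)))
        else:
            lo, hi = bounds.get(key, (1e-300, 1e300))
            params.add(name, value=np.log10(max(value, 1e-12)),
                       min=np.log10(max(lo, 1e-300)), max=np.log10(hi))

    for key in share:
        add(f"s_{key}", float(np.median([getattr(p, key) for p in singles])), key)
    for i, p in enumerate(singles):
        for key in per_curve:
            add(f"c{i}_{key}", getattr(p, key), key)

    ws = []
    for c in curves:
        if weights == "auto" and c.sd is not None and np.all(c.sd > 0):
            ws.append(1.0 / c.sd)
        else:
            ws.append(np.ones_like(c.lags))

    def unpack_one(v, key):
        v = float(np.clip(v, -300, 300))
        return 1.0 / (1.0 + np.exp(-v)) if key == "F" else 10.0**v

    def params_for(i, pv):
        kw = {}
        for key in share:
            kw[key] = unpack_one(pv[f"s_{key}"], key)
        for key in per_curve:
            kw[key] = unpack_one(pv[f"c{i}_{key}"], key)
        return EmpiricalParams(**kw)

    def resid(pars):
        pv = {k: pars[k].value for k in pars}
        out = []
        for i, c in enumerate(curves):
            model = eval_empirical_acf(params_for(i, pv), c.lags)
            out.append((model - c.amplitudes) * ws[i])
        return np.concatenate(out)

    res = lmfit.minimize(resid, params, method="least_squares")
    pv = {k: res.params[k].value for k in res.params}
    fitted = [params_for(i, pv).canonical() for i in range(len(curves))]
    n_points = sum(len(c) for c in curves)
    n_free = len(params)
    chi2 = float(res.chisqr)
    diag = FitDiagnostics(
        ssr=chi2, chi2=chi2,
        chi2_dof=chi2 / max(n_points - n_free, 1),
        n_points=n_points, n_free=n_free,
        success=bool(res.success), n_starts=n_starts, message="global envelope fit",
    )
    return fitted, diag


# ---------------------------------------------------------------------------
# tabular IO


def _resolve_columns(df: pd.DataFrame, dialect: dict[str, str] | None) -> dict[str, str]:
    dialect = dict(dialect or {})
    mapping = {}
    for std in STANDARD_COLUMNS:
        col = dialect.get(std, std)
        if col in df.columns:
            mapping[std] = col
    for required in ("lag_s", "g"):
        if required not in mapping:
            raise FormatError(f"missing required column {required!r}")
    return mapping


def load_acf_table(path, dialect: dict[str, str] | None = None) -> list[ACFCurve]:
    """Load autocorrelation curves from a delimited table.

    One :class:`ACFCurve` is produced per ``curve_id`` group (the whole
    table if absent).  ``dialect`` maps the standard column names
    (``lag_s``, ``g``, ``sd``, ``curve_id``, ``construct``, ``trp``,
    ``trp_mM``, ``condition``, ``replicate``) to the file's own headers.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df, dialect)
    for numeric in ("lag_s", "g", "sd", "trp_mM"):
        if numeric in cols:
            try:
                df[cols[numeric]] = pd.to_numeric(df[cols[numeric]])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric values in column {cols[numeric]!r}") from exc
    if (df[cols["lag_s"]] <= 0).any():
        row = int(df.index[df[cols["lag_s"]] <= 0][0])
        raise ValueError(f"non-positive lag at row {row}")
    groups = (
        [(None, df)] if "curve_id" not in cols else df.groupby(cols["curve_id"], sort=True)
    )
    curves = []
    for cid, sub in groups:
        sub = sub.sort_values(cols["lag_s"])

        def meta(name, default, cast=str):
            return cast(sub[cols[name]].iloc[0]) if name in cols else default

        curves.append(
            ACFCurve(
                lags=sub[cols["lag_s"]].to_numpy(),
                amplitudes=sub[cols["g"]].to_numpy(),
                sd=sub[cols["sd"]].to_numpy() if "sd" in cols else None,
                construct=meta("construct", ""),
                trp_present=meta("trp", True, lambda v: str(v).lower() in ("present", "true", "1", "w6")),
                trp_mM=meta("trp_mM", 0.0, float),
                condition=meta("condition", ""),
                replicate=meta("replicate", "0"),
                curve_id="" if cid is None else str(cid),
            )
        )
    return curves


def write_acf_table(curves: list[ACFCurve], path) -> None:
    """Write curves to CSV in the standard column layout."""
    frames = []
    for i, c in enumerate(curves):
        frames.append(
            pd.DataFrame(
                {
                    "lag_s": c.lags,
                    "g": c.amplitudes,
                    "sd": c.sd if c.sd is not None else np.nan,
                    "curve_id": c.curve_id or f"curve{i}",
                    "construct": c.construct,
                    "trp": "present" if c.trp_present else "absent",
                    "trp_mM": c.trp_mM,
                    "condition": c.condition,
                    "replicate": c.replicate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def params_table(results: dict[str, tuple[EmpiricalParams, FitDiagnostics]]) -> pd.DataFrame:
    """Fitted-parameter table (one row per curve) for CSV export."""
    rows = []
    for cid, (p, d) in results.items():
        row = {"curve_id": cid, **dataclasses.asdict(p)}
        row.update(chi2=d.chi2, chi2_dof=d.chi2_dof, n_points=d.n_points)
        rows.append(row)
    return pd.DataFrame(rows)
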