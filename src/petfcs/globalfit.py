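"""Global fitting of stripped dynamic decays to a kinetic network.

Many decays (constructs x Trp conditions) are fitted simultaneously to
one scheme preset.  Per-construct rate constants can be locked at fixed
values, linked (one shared estimate across a group of constructs), or
scaled by a free-Trp concentration (bimolecular titration edges).  Rates
are optimized in log10 space; standard errors come from the covariance
matrix at the optimum; models are compared by chi^2/DoF; confidence
intervals come from 1-D profile scans against a constant normalized-chi^2
contour (the "FitSpace" convention: the interval is the region where
chi^2_min / chi^2_profile stays above the contour value, 0.833 by
default).

The published linking protocol for nascent-chain panels is available as
named presets (``paper-5eH``, ``paper-5eO``):

* dye–Trp dissociation rates locked (2.2 µs^-1 for 5e-H, 2.0 for 5e-O);
* ribosome-dequenching rates shared across all constructs;
* D-state quenching on-rates linked pairwise between the wt and 4xA
  variants of the same length (and loop variants to wt of that length);
* C-state on-rates shared across all constructs;
* any construct matching both "112" and "4xa" keeps all its rates
  separate except the shared ribosome-dequenching rates.

Construct labels are parsed as ``<name><length>_<variant>`` (e.g.
``hemk70_wt``, ``hemk102_4xa``, ``hemk112_loop``) when building presets;
explicit link configurations bypass the parsing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .acf import DynamicDecay
from .kinetics import (
    KineticScheme,
    RateSet,
    build_scheme,
    simulate_dynamic_component,
)


class LinkError(ValueError):
    """Invalid locking/linking configuration."""


@dataclass
class LinkConfig:
    """Locking and linking rules applied across a construct panel.

    ``lock``: rate name -> value (s^-1), applied to every construct.
    ``share_all``: rate names estimated once for the whole panel.
    ``groups``: (rate name, [constructs]) sharing one estimate.
    ``tie``: (rate_a, rate_b) pairs estimated as one parameter within each
    construct (e.g. the dye-Trp dissociation from the Wc and Wd states,
    which is a property of the stacked pair, not of the conformation).
    ``bimolecular``: rate names whose free parameter is a second-order
    constant (s^-1 mM^-1), multiplied by each curve's trp_mM.
    """

    lock: dict[str, float] = field(default_factory=dict)
    share_all: tuple[str, ...] = ()
    groups: tuple[tuple[str, tuple[str, ...]], ...] = ()
    tie: tuple[tuple[str, str], ...] = ()
    bimolecular: tuple[str, ...] = ()
    name: str = "custom"


_LABEL_RE = re.compile(r"(\d+)")


def _length_of(construct: str) -> str:
    m = _LABEL_RE.search(construct)
    return m.group(1) if m else construct


def paper_links(scheme_preset: str, constructs: list[str]) -> LinkConfig:
    """The published locking/linking protocol for a construct panel."""
    if scheme_preset == "5e-H":
        lock = {"koff_Wc": 2.2e6, "koff_Wd": 2.2e6}
        koff_r = ("koff_Rc", "koff_Rd")
        kon_c = ("kon_Wc", "kon_Rc")
        kon_d = ("kon_Wd", "kon_Rd")
    elif scheme_preset == "5e-O":
        lock = {"koff_Wc": 2.0e6, "koff_Wd": 2.0e6}
        koff_r = ("koff_Rc", "koff_Rd")
        kon_c = ("kon_Wc", "kon_Rc")
        kon_d = ("kon_Wd", "kon_Rd")
    elif scheme_preset in ("2e", "3e"):
        # reduced schemes have only D-state quenching edges; apply the same
        # protocol: lock the dye-Trp dissociation, share ribosome
        # dequenching panel-wide, link the quenching on-rates pairwise
        # within a length (they reflect the dye-quencher pair and the
        # chain's position, not the scheme)
        lock = {"koff_W": 2.2e6}
        koff_r = ("koff_R",)
        kon_c = ()
        kon_d = ("kon_W", "kon_R")
    else:
        raise LinkError(f"no published linking preset for scheme {scheme_preset!r}")

    special = [c for c in constructs if "112" in c and "4xa" in c.lower()]
    regular = [c for c in constructs if c not in special]
    groups: list[tuple[str, tuple[str, ...]]] = []
    # ribosome dequenching shared across the entire panel (incl. special)
    for r in koff_r:
        groups.append((r, tuple(constructs)))
    # C-state on-rates shared across all regular constructs
    for r in kon_c:
        if len(regular) > 1:
            groups.append((r, tuple(regular)))
    # D-state on-rates linked within a length (wt/4xA/loop of equal length)
    by_length: dict[str, list[str]] = {}
    for c in regular:
        by_length.setdefault(_length_of(c), []).append(c)
    for r in kon_d:
        for members in by_length.values():
            if len(members) > 1:
                groups.append((r, tuple(members)))
    return LinkConfig(lock=lock, groups=tuple(groups), name=f"paper-{scheme_preset}")


def resolve_links(links, scheme_preset: str, constructs: list[str]) -> LinkConfig:
    if isinstance(links, LinkConfig):
        return links
    if links is None:
        return LinkConfig(name="independent")
    if isinstance(links, str):
        if links.startswith("paper"):
            return paper_links(scheme_preset, constructs)
        raise LinkError(f"unknown links preset {links!r}")
    if isinstance(links, dict):
        return LinkConfig(
            lock=dict(links.get("lock", {})),
            share_all=tuple(links.get("share_all", ())),
            groups=tuple((r, tuple(cs)) for r, cs in links.get("groups", ())),
            bimolecular=tuple(links.get("bimolecular", ())),
            name=links.get("name", "custom"),
        )
    raise LinkError(f"cannot interpret links config of type {type(links)}")


# ---------------------------------------------------------------------------


def _pname(rate: str, construct: str) -> str:
    return re.sub(r"\W", "_", f"{rate}__{construct}")


#: initialization windows (s^-1) by rate-name pattern: the instrument's
#: µs-sensitivity window split by the physical role of each rate class
_START_WINDOWS = (
    (re.compile(r"^k_(CD|DC)$"), (3e4, 3e6)),
    (re.compile(r"^kon_[WR]c$|^kon_[WR]$"), (1e4, 1e6)),
    (re.compile(r"^kon_[WR]d$"), (1e6, 2e7)),
    (re.compile(r"^koff_"), (1e5, 3e6)),
)
_FALLBACK_WINDOW = (1e4, 1e7)


def start_window(rate: str) -> tuple[float, float]:
    for pat, win in _START_WINDOWS:
        if pat.match(rate):
            return win
    return _FALLBACK_WINDOW


@dataclass
class FitProblem:
    """A set of decays plus the parameter structure tying them together."""

    scheme: KineticScheme
    decays: list[DynamicDecay]
    links: LinkConfig
    weighting: str = "sd"  # "sd" (1/sd where available) or "uniform"
    #: "correlation": parameter-free normalized fluctuation ACF;
    #: "amplitude-fit": species sums with one free amplitude coefficient
    #: per state, shared across every decay of the problem
    mode: str = "correlation"
    #: log10 bounds on free rates (s^-1)
    log_bounds: tuple[float, float] = (2.0, 9.0)

    def __post_init__(self) -> None:
        if not self.decays:
            raise LinkError("problem has no decays")
        rate_names = set(self.scheme.rate_names)
        for rule_set in (self.links.lock, dict.fromkeys(self.links.share_all)):
            unknown = set(rule_set) - rate_names
            if unknown:
                raise LinkError(f"links reference unknown rates: {sorted(unknown)}")
        for pair in self.links.tie:
            unknown = set(pair) - rate_names
            if unknown:
                raise LinkError(f"tie references unknown rates: {sorted(unknown)}")
        for rate, cs in self.links.groups:
            if rate not in rate_names:
                raise LinkError(f"link group references unknown rate {rate!r}")
            missing = set(cs) - set(self.constructs)
            if missing:
                raise LinkError(f"link group for {rate!r} references constructs without data: {sorted(missing)}")
        seen_in_group: dict[str, set[str]] = {}
        for rate, cs in self.links.groups:
            prev = seen_in_group.setdefault(rate, set())
            if prev & set(cs):
                raise LinkError(f"construct appears in two link groups for {rate!r}")
            prev.update(cs)

    @property
    def constructs(self) -> list[str]:
        out = []
        for d in self.decays:
            if d.construct not in out:
                out.append(d.construct)
        return out

    # -- parameter bookkeeping -------------------------------------------

    def parameter_map(self) -> dict[tuple[str, str], tuple[str, str | float]]:
        """(construct, rate) -> ("locked", value) | ("free", param name)."""
        cached = getattr(self, "_pmap_cache", None)
        if cached is not None:
            return cached
        out: dict[tuple[str, str], tuple[str, str | float]] = {}
        group_rep: dict[tuple[str, str], str] = {}
        for rate, cs in self.links.groups:
            rep = _pname(rate, cs[0])
            for c in cs:
                group_rep[(c, rate)] = rep
        for c in self.constructs:
            for rate in self.scheme.rate_names:
                if rate in self.links.lock:
                    out[(c, rate)] = ("locked", float(self.links.lock[rate]))
                elif rate in self.links.share_all:
                    out[(c, rate)] = ("free", _pname(rate, "shared"))
                elif (c, rate) in group_rep:
                    out[(c, rate)] = ("free", group_rep[(c, rate)])
                else:
                    out[(c, rate)] = ("free", _pname(rate, c))
        for rate_a, rate_b in self.links.tie:
            for c in self.constructs:
                out[(c, rate_b)] = out[(c, rate_a)]
        self._pmap_cache = out
        return out

    def amplitude_names(self) -> list[str]:
        if self.mode != "amplitude-fit":
            return []
        return [f"amp__{s}" for s in self.scheme.states]

    def free_parameter_names(self) -> list[str]:
        seen: list[str] = []
        for (c, rate), (kind, ref) in self.parameter_map().items():
            if kind == "free" and ref not in seen:
                seen.append(ref)
        return seen + self.amplitude_names()

    def n_points(self) -> int:
        return sum(len(d.lags) for d in self.decays)

    def weights_for(self, d: DynamicDecay) -> np.ndarray:
        if self.weighting == "sd" and d.sd is not None and np.all(d.sd > 0):
            return 1.0 / d.sd
        return np.ones_like(d.lags)

    # -- model evaluation -------------------------------------------------

    def rates_for(self, construct: str, values: dict[str, float], trp_mM: float,
                  trp_present: bool) -> RateSet:
        pmap = self.parameter_map()
        rates = {}
        for rate in self.scheme.rate_names:
            kind, ref = pmap[(construct, rate)]
            v = ref if kind == "locked" else values[ref]
            if rate in self.links.bimolecular:
                v = v * trp_mM
            elif not trp_present and rate in self.scheme.trp_on_rates:
                v = 0.0
            rates[rate] = v
        return RateSet(values=rates)

    def residuals(self, values: dict[str, float]) -> np.ndarray:
        # Per-curve memo: finite-difference Jacobians perturb one parameter
        # at a time, leaving most curves' rate sets (and hence their model
        # curves) unchanged between calls.
        cache = getattr(self, "_ycache", None)
        if cache is None:
            cache = self._ycache = {}
        amps = None
        amp_key = ()
        if self.mode == "amplitude-fit":
            amps = {s: values[f"amp__{s}"] for s in self.scheme.states}
            amp_key = tuple(amps[s] for s in self.scheme.states)
        out = []
        for i, d in enumerate(self.decays):
            rates = self.rates_for(d.construct, values, d.trp_mM, d.trp_present)
            key = (i, amp_key, tuple(rates.values[r] for r in self.scheme.rate_names))
            y = cache.get(key)
            if y is None:
                y = simulate_dynamic_component(
                    self.scheme, rates, d.lags, mode=self.mode, amplitudes=amps
                ).values
                if len(cache) > 4096:
                    cache.clear()
                cache[key] = y
            out.append((y - d.values) * self.weights_for(d))
        return np.concatenate(out)


def assemble_problem(
    decays: list[DynamicDecay],
    scheme,
    links="paper",
    weighting: str = "sd",
    mode: str = "correlation",
) -> FitProblem:
    """Validate and bundle decays + scheme + linking into a FitProblem."""
    scheme = build_scheme(scheme)
    if mode not in ("correlation", "amplitude-fit"):
        raise ValueError(f"unknown fit mode {mode!r}")
    constructs = []
    for d in decays:
        if d.construct not in constructs:
            constructs.append(d.construct)
    link_cfg = resolve_links(links, scheme.preset, constructs)
    return FitProblem(scheme=scheme, decays=decays, links=link_cfg,
                      weighting=weighting, mode=mode)


@dataclass
class FitResult:
    problem: FitProblem
    minimizer_result: lmfit.minimizer.MinimizerResult
    chi2: float
    dof: int
    n_starts: int

    @property
    def chi2_dof(self) -> float:
        return self.chi2 / self.dof

    @property
    def success(self) -> bool:
        return bool(self.minimizer_result.success)

    def parameter_values(self) -> dict[str, float]:
        out = {}
        for name in self.problem.free_parameter_names():
            v = self.minimizer_result.params[name].value
            out[name] = v if _is_amp(name) else 10.0**v
        return out

    def parameter_se(self) -> dict[str, float | None]:
        out = {}
        for name in self.problem.free_parameter_names():
            p = self.minimizer_result.params[name]
            if p.stderr is None or not np.isfinite(p.stderr):
                out[name] = None
            elif _is_amp(name):
                out[name] = p.stderr
            else:
                out[name] = 10.0**p.value * np.log(10.0) * p.stderr
        return out

    def amplitudes(self) -> dict[str, float] | None:
        """Fitted species amplitude coefficients (amplitude-fit mode)."""
        if self.problem.mode != "amplitude-fit":
            return None
        vals = self.parameter_values()
        return {s: vals[f"amp__{s}"] for s in self.problem.scheme.states}

    def rates_table(self) -> pd.DataFrame:
        """Per construct and rate: value, SE, status, link group."""
        values = self.parameter_values()
        ses = self.parameter_se()
        rows = []
        for (c, rate), (kind, ref) in self.problem.parameter_map().items():
            if kind == "locked":
                rows.append(
                    {"construct": c, "rate": rate, "value": ref, "se": np.nan,
                     "status": "locked", "param": ""}
                )
            else:
                rows.append(
                    {
                        "construct": c,
                        "rate": rate,
                        "value": values[ref],
                        "se": np.nan if ses[ref] is None else ses[ref],
                        "status": "free",
                        "param": ref,
                    }
                )
        return pd.DataFrame(rows)

    def per_curve_residuals(self) -> list[np.ndarray]:
        values = self.parameter_values()
        out = []
        for d in self.problem.decays:
            rates = self.problem.rates_for(d.construct, values, d.trp_mM, d.trp_present)
            y = simulate_dynamic_component(self.problem.scheme, rates, d.lags).values
            out.append((y - d.values) * self.problem.weights_for(d))
        return out


class GlobalFitFailure(RuntimeError):
    def __init__(self, message: str, best: FitResult | None = None):
        super().__init__(message)
        self.best = best


def compute_chi2_dof(problem: FitProblem, values: dict[str, float]) -> tuple[float, float]:
    """chi^2 over all curves and chi^2/DoF for given free-parameter values.

    ``values`` maps free parameter names (see
    ``problem.free_parameter_names()``) to rates in s^-1.
    """
    n_free = len(problem.free_parameter_names())
    dof = problem.n_points() - n_free
    if dof <= 0:
        raise ValueError(f"nonpositive DoF: {problem.n_points()} points, {n_free} free")
    r = problem.residuals(values)
    chi2 = float(r @ r)
    return chi2, chi2 / dof


def _is_amp(name: str) -> bool:
    return name.startswith("amp__")


def _make_params(problem: FitProblem, start: dict[str, float]) -> lmfit.Parameters:
    """Rates enter in log10 space; amplitude coefficients stay linear."""
    lo, hi = problem.log_bounds
    params = lmfit.Parameters()
    for name in problem.free_parameter_names():
        if _is_amp(name):
            params.add(name, value=float(start[name]), min=0.0, max=1e3)
        else:
            params.add(name, value=float(np.clip(start[name], lo, hi)), min=lo, max=hi)
    return params


def _residual_vector(params: lmfit.Parameters, problem: FitProblem) -> np.ndarray:
    values = {
        name: (params[name].value if _is_amp(name) else 10.0 ** params[name].value)
        for name in params
    }
    return problem.residuals(values)


def _draw_starts(problem: FitProblem, n_starts: int, seed: int,
                 init: dict[str, float] | None) -> list[dict[str, float]]:
    names = problem.free_parameter_names()
    rate_of = {}
    for (c, rate), (kind, ref) in problem.parameter_map().items():
        if kind == "free":
            rate_of[ref] = rate

    def window(ref):
        rate = rate_of[ref]
        if rate in problem.links.bimolecular:
            return (1e3, 1e6)  # second-order constant, s^-1 mM^-1
        return start_window(rate)

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        # partial inits allowed: missing parameters drop to a window draw
        s = {}
        for n in names:
            if _is_amp(n):
                s[n] = init.get(n, 1.0)
            elif n in init:
                s[n] = np.log10(init[n])
            else:
                wlo, whi = window(n)
                s[n] = rng.uniform(np.log10(wlo), np.log10(whi))
        starts.append(s)
    first_random = 1 if init is not None else 0
    for k in range(first_random, n_starts):
        s = {}
        for n in names:
            if _is_amp(n):
                s[n] = 1.0 if k == 0 else float(rng.uniform(0.2, 3.0))
            else:
                wlo, whi = window(n)
                s[n] = rng.uniform(np.log10(wlo), np.log10(whi))
        starts.append(s)
    return starts


def fit_global(
    problem: FitProblem,
    n_starts: int = 8,
    seed: int = 0,
    init: dict[str, float] | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Minimize the global weighted chi^2 with a seeded multi-start.

    Starting points are drawn log-uniformly inside per-rate-class physical
    windows (conformational exchange, C-state quenching, D-state
    quenching, dequenching); ``init`` (free parameter name -> rate in
    s^-1) adds a caller-supplied first start.  The best converged start by
    chi^2 wins; ties break toward the lexicographically smallest parameter
    vector.  Standard errors are derived from the covariance matrix at the
    optimum (in log10 space, delta-converted to rate units).
    """
    names = problem.free_parameter_names()
    if not names:
        raise ValueError("no free parameters")
    dof = problem.n_points() - len(names)
    if dof <= 0:
        raise ValueError("nonpositive DoF")
    best = None
    for s in _draw_starts(problem, n_starts, seed, init):
        params = _make_params(problem, s)
        try:
            res = lmfit.minimize(
                _residual_vector,
                params,
                args=(problem,),
                method="least_squares",
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        chi2 = float(res.chisqr)
        vec = tuple(res.params[n].value for n in names)
        if best is None or chi2 < best[0] - 1e-12 * max(best[0], 1.0) or (
            abs(chi2 - best[0]) <= 1e-12 * max(best[0], 1.0) and vec < best[1]
        ):
            best = (chi2, vec, res)
    if best is None:
        raise GlobalFitFailure("no start converged")
    chi2, _, res = best
    return FitResult(problem=problem, minimizer_result=res, chi2=chi2, dof=dof,
                     n_starts=n_starts)


def scan_confidence(
    result: FitResult,
    param_name: str,
    contour: float = 0.833,
    span_decades: float = 1.5,
    n_grid: int = 25,
) -> tuple[float | None, float | None]:
    """Profile-likelihood interval at a constant normalized-chi^2 contour.

    The parameter is stepped over a log grid around its optimum; at each
    step all other free parameters are re-optimized (warm-started from the
    global optimum).  The interval is the region where
    chi^2_min / chi^2_profile >= ``contour`` (so chi^2 may grow by a
    factor 1/contour before the boundary is crossed).  ``None`` marks a
    bound that stays open within the scanned span.
    """
    problem = result.problem
    names = problem.free_parameter_names()
    if param_name not in names:
        raise ValueError(f"{param_name!r} is not a free parameter of this fit")
    if not 0 < contour < 1:
        raise ValueError("contour must lie in (0, 1)")
    chi2_min = result.chi2
    limit = chi2_min / contour
    best_log = {n: result.minimizer_result.params[n].value for n in names}
    center = best_log[param_name]

    def profile_chi2(logv: float) -> float:
        params = lmfit.Parameters()
        lo, hi = problem.log_bounds
        for n in names:
            if n == param_name:
                params.add(n, value=logv, vary=False)
            else:
                params.add(n, value=best_log[n], min=lo, max=hi)
        if len(names) == 1:
            r = _residual_vector(params, problem)
            return float(r @ r)
        res = lmfit.minimize(_residual_vector, params, args=(problem,),
                             method="least_squares")
        return float(res.chisqr)

    def crossing(direction: int) -> float | None:
        grid = center + direction * np.linspace(0.0, span_decades, n_grid)[1:]
        prev_v, prev_chi = center, chi2_min
        for v in grid:
            chi = profile_chi2(v)
            if chi >= limit:
                # linear interpolation in chi^2 between the last two points
                frac = (limit - prev_chi) / (chi - prev_chi)
                return 10.0 ** (prev_v + frac * (v - prev_v))
            prev_v, prev_chi = v, chi
        return None  # open-ended within the scanned span

    return crossing(-1), crossing(+1)


def _base_rate(rate: str) -> str:
    """Strip the conformation suffix: kon_Rc/kon_Rd -> kon_R."""
    if re.match(r"^k(on|off)_[WR][cd]$", rate):
        return rate[:-1]
    return rate


def nested_init(problem: FitProblem, prev: FitResult) -> dict[str, float]:
    """Warm-start values for a richer scheme from a simpler scheme's fit.

    Rates are matched by construct, exactly by name first and then by base
    rate name (the shared/split quenched-state naming collapses under
    :func:`_base_rate`).  In the reduced schemes only the D state is
    quenched, so a base-name match seeds only the D-state on-rate of a
    five-equilibria scheme; the C-state on-rates start negligibly small
    (1e3 s^-1), which makes the warm start reproduce the simpler scheme's
    optimum almost exactly before the new equilibria are opened up.
    Dequenching rates are shared per quencher and map to both split
    states.  Remaining parameters fall back to the window draw.
    """
    table = prev.rates_table()
    exact: dict[tuple[str, str], float] = {}
    by_base: dict[tuple[str, str], float] = {}
    for _, r in table.iterrows():
        exact[(r["construct"], r["rate"])] = float(r["value"])
        by_base[(r["construct"], _base_rate(r["rate"]))] = float(r["value"])
    init: dict[str, float] = {}
    for (c, rate), (kind, ref) in problem.parameter_map().items():
        if kind != "free" or ref in init:
            continue
        v = exact.get((c, rate))
        if v is None:
            base = _base_rate(rate)
            if base != rate and rate.startswith("kon_") and rate.endswith("c"):
                v = 1e3  # new C-state quenching equilibrium: start closed
            else:
                v = by_base.get((c, base))
        if v is not None and v > 0:
            init[ref] = v
    return init


def compare_models(
    decays: list[DynamicDecay],
    schemes: tuple[str, ...] = ("2e", "3e", "5e-O", "5e-H"),
    links="paper",
    n_starts: int = 6,
    seed: int = 0,
    inits: dict[str, dict[str, float]] | None = None,
    mode: str = "correlation",
) -> pd.DataFrame:
    """Fit several scheme presets to the same decays; rank by chi^2/DoF.

    Each scheme uses its own published linking preset when
    ``links="paper"``.  Schemes are fitted in order of increasing state
    count and each fit warm-starts from the best simpler scheme (nested
    models can only improve from there), in addition to its random
    multi-start.  Schemes that fail to fit are reported with ``ok=False``
    and excluded from the ranking order.
    """
    rows = []
    results = {}
    order = sorted(schemes, key=lambda s: build_scheme(s).n_states)
    prev_fit: FitResult | None = None
    for preset in order:
        try:
            problem = assemble_problem(decays, preset, links=links, mode=mode)
            init = (inits or {}).get(preset)
            if init is None and prev_fit is not None:
                init = nested_init(problem, prev_fit)
            fit = fit_global(
                problem,
                n_starts=n_starts,
                seed=seed,
                init=init or None,
            )
            if prev_fit is None or fit.chi2_dof < prev_fit.chi2_dof:
                prev_fit = fit
            rows.append(
                {"scheme": preset, "chi2": fit.chi2, "dof": fit.dof,
                 "chi2_dof": fit.chi2_dof, "n_free": len(problem.free_parameter_names()),
                 "ok": True}
            )
            results[preset] = fit
        except Exception as exc:  # reported, excluded from ranking
            rows.append(
                {"scheme": preset, "chi2": np.nan, "dof": np.nan, "chi2_dof": np.nan,
                 "n_free": np.nan, "ok": False, "error": str(exc)}
            )
    table = pd.DataFrame(rows).sort_values(
        by=["ok", "chi2_dof"], ascending=[False, True], ignore_index=True
    )
    table.attrs["fits"] = results
    if table["ok"].any():
        table.attrs["winner"] = table.loc[table["ok"], "scheme"].iloc[0]
    return table
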