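"""First-order kinetic networks for nascent-chain PET quenching dynamics.

A nascent chain on the ribosome is modelled as a continuous-time Markov
jump process over a small set of conformational/photophysical states.  Each
state is either fluorescent (brightness 1) or statically quenched
(brightness 0; dye stacked on a Trp side chain or on a ribosome-surface
quencher).  The autocorrelation decay of the fluorescence fluctuations is
fully determined by the generator matrix of the network, so the model
predictions used in fitting are linear-algebra evaluations, not stochastic
simulations.

Four named topologies are provided:

``2e``
    states {D, R, W}; D fluorescent, edges D<->R and D<->W (a single
    nascent-chain conformation quenched either by the ribosome or by Trp).
``3e``
    adds a second fluorescent conformation C with edge C<->D.
``5e-O``
    states {C, D, W, R}; quenched states shared between conformations,
    edges C<->D, C<->W, C<->R, D<->W, D<->R (cyclic topology).
``5e-H``
    states {C, D, Wc, Wd, Rc, Rd}; one quenched state per conformation and
    quencher, edges C<->D, C<->Wc, C<->Rc, D<->Wd, D<->Rd (tree topology).

Rate-name conventions: ``k_CD``/``k_DC`` are the conformational exchange
rates C->D / D->C; ``kon_X``/``koff_X`` are quenched-complex formation and
dissociation rates for quenched state X.  All rates are in s^-1; Trp
quenching on-rates may be declared bimolecular (s^-1 mM^-1) and scaled by a
free-Trp concentration with :func:`apply_trp_concentration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg


class SchemeError(ValueError):
    """Invalid kinetic-scheme topology or incomplete rate set."""


@dataclass(frozen=True)
class Edge:
    """A reversible transition between two states.

    ``forward`` names the rate of state_a -> state_b, ``reverse`` the rate
    of state_b -> state_a.
    """

    state_a: str
    state_b: str
    forward: str
    reverse: str


@dataclass(frozen=True)
class KineticScheme:
    """A named first-order state network with per-state brightness."""

    states: tuple[str, ...]
    brightness: tuple[int, ...]
    edges: tuple[Edge, ...]
    preset: str = "custom"
    #: forward rate names that represent Trp quenching (may be bimolecular)
    trp_on_rates: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemeError("a scheme needs at least two states")
        if len(set(self.states)) != len(self.states):
            raise SchemeError("duplicate state labels")
        if len(self.brightness) != len(self.states):
            raise SchemeError("brightness must match states")
        if not any(self.brightness):
            raise SchemeError("at least one state must be fluorescent")
        if not all(b in (0, 1) for b in self.brightness):
            raise SchemeError("brightness flags must be 0 or 1")
        names = [e.forward for e in self.edges] + [e.reverse for e in self.edges]
        if len(set(names)) != len(names):
            raise SchemeError("rate names must be unique")
        pairs = {frozenset((e.state_a, e.state_b)) for e in self.edges}
        if len(pairs) != len(self.edges):
            raise SchemeError("duplicate edges between a state pair")
        for e in self.edges:
            if e.state_a not in self.states or e.state_b not in self.states:
                raise SchemeError(f"edge references unknown state: {e}")
        # undirected connectivity
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for e in self.edges:
            adj[e.state_a].add(e.state_b)
            adj[e.state_b].add(e.state_a)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(self.states):
            raise SchemeError("network is disconnected")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def rate_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.edges:
            out.extend((e.forward, e.reverse))
        return tuple(out)

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    @property
    def brightness_vector(self) -> np.ndarray:
        return np.asarray(self.brightness, dtype=float)


@dataclass
class RateSet:
    """Named rate constants (s^-1) for a scheme.

    Names listed in ``bimolecular`` hold second-order constants
    (s^-1 mM^-1) and must be converted to pseudo-first-order values with
    :func:`apply_trp_concentration` before building a generator matrix.
    """

    values: dict[str, float]
    bimolecular: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"rate {name} is negative: {v}")
        self.bimolecular = frozenset(self.bimolecular)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def validate_for(self, scheme: KineticScheme) -> None:
        missing = set(scheme.rate_names) - set(self.values)
        if missing:
            raise SchemeError(f"missing rates for scheme {scheme.preset}: {sorted(missing)}")
        if self.bimolecular:
            raise SchemeError(
                "bimolecular rates present; apply a Trp concentration first: "
                f"{sorted(self.bimolecular)}"
            )


@dataclass(frozen=True)
class StateOccupancy:
    """Equilibrium probability per state."""

    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must be nonnegative and sum to 1")

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.states.index(label)])


@dataclass
class SpectrumResult:
    occupancy: StateOccupancy
    eigenvalues: np.ndarray
    generator: np.ndarray


@dataclass
class DecayCurve:
    """Predicted dynamic ACF component y(t) for a scheme + rates."""

    times: np.ndarray
    values: np.ndarray
    mode: str = "correlation"
    amplitudes: dict[str, float] | None = None


_PRESET_BUILDERS = {}


def _preset(name):
    def deco(fn):
        _PRESET_BUILDERS[name] = fn
        return fn

    return deco


@_preset("2e")
def _build_2e() -> KineticScheme:
    return KineticScheme(
        states=("D", "R", "W"),
        brightness=(1, 0, 0),
        edges=(
            Edge("D", "R", "kon_R", "koff_R"),
            Edge("D", "W", "kon_W", "koff_W"),
        ),
        preset="2e",
        trp_on_rates=frozenset({"kon_W"}),
    )


@_preset("3e")
def _build_3e() -> KineticScheme:
    return KineticScheme(
        states=("C", "D", "R", "W"),
        brightness=(1, 1, 0, 0),
        edges=(
            Edge("C", "D", "k_CD", "k_DC"),
            Edge("D", "R", "kon_R", "koff_R"),
            Edge("D", "W", "kon_W", "koff_W"),
        ),
        preset="3e",
        trp_on_rates=frozenset({"kon_W"}),
    )


@_preset("5e-O")
def _build_5eo() -> KineticScheme:
    return KineticScheme(
        states=("C", "D", "W", "R"),
        brightness=(1, 1, 0, 0),
        edges=(
            Edge("C", "D", "k_CD", "k_DC"),
            Edge("C", "W", "kon_Wc", "koff_Wc"),
            Edge("C", "R", "kon_Rc", "koff_Rc"),
            Edge("D", "W", "kon_Wd", "koff_Wd"),
            Edge("D", "R", "kon_Rd", "koff_Rd"),
        ),
        preset="5e-O",
        trp_on_rates=frozenset({"kon_Wc", "kon_Wd"}),
    )


@_preset("5e-H")
def _build_5eh() -> KineticScheme:
    return KineticScheme(
        states=("C", "D", "Wc", "Wd", "Rc", "Rd"),
        brightness=(1, 1, 0, 0, 0, 0),
        edges=(
            Edge("C", "D", "k_CD", "k_DC"),
            Edge("C", "Wc", "kon_Wc", "koff_Wc"),
            Edge("C", "Rc", "kon_Rc", "koff_Rc"),
            Edge("D", "Wd", "kon_Wd", "koff_Wd"),
            Edge("D", "Rd", "kon_Rd", "koff_Rd"),
        ),
        preset="5e-H",
        trp_on_rates=frozenset({"kon_Wc", "kon_Wd"}),
    )


@_preset("two-state")
def _build_two_state() -> KineticScheme:
    """Bright <-> dark toy network (closed-form reference)."""
    return KineticScheme(
        states=("B", "Q"),
        brightness=(1, 0),
        edges=(Edge("B", "Q", "kon", "koff"),),
        preset="two-state",
    )


PRESETS = tuple(_PRESET_BUILDERS)


def build_scheme(preset_or_spec) -> KineticScheme:
    """Build a validated scheme from a preset tag or an explicit spec.

    Custom specs are mappings with keys ``states`` (label -> brightness)
    and ``edges`` (list of [state_a, state_b, forward, reverse]).
    """
    if isinstance(preset_or_spec, KineticScheme):
        return preset_or_spec
    if isinstance(preset_or_spec, str):
        try:
            return _PRESET_BUILDERS[preset_or_spec]()
        except KeyError:
            raise SchemeError(
                f"unknown preset {preset_or_spec!r}; known: {sorted(_PRESET_BUILDERS)}"
            ) from None
    spec = dict(preset_or_spec)
    states = tuple(spec["states"])
    brightness = tuple(int(spec["states"][s]) for s in states)
    edges = tuple(Edge(*e) for e in spec["edges"])
    return KineticScheme(
        states=states,
        brightness=brightness,
        edges=edges,
        preset=spec.get("preset", "custom"),
        trp_on_rates=frozenset(spec.get("trp_on_rates", ())),
    )


def apply_trp_concentration(rates: RateSet, trp_mM: float) -> RateSet:
    """Scale bimolecular Trp-quenching on-rates to pseudo-first order.

    Every rate flagged bimolecular (s^-1 mM^-1) is multiplied by the free
    Trp concentration; all other rates pass through unchanged.
    """
    if trp_mM < 0:
        raise ValueError(f"negative Trp concentration: {trp_mM}")
    values = dict(rates.values)
    for name in rates.bimolecular:
        values[name] = values[name] * trp_mM
    return RateSet(values=values, bimolecular=frozenset())


def generator_matrix(scheme: KineticScheme, rates: RateSet) -> np.ndarray:
    """Column-stochastic generator K with dx/dt = K x; column sums are 0."""
    rates.validate_for(scheme)
    n = scheme.n_states
    K = np.zeros((n, n))
    for e in scheme.edges:
        a, b = scheme.state_index(e.state_a), scheme.state_index(e.state_b)
        K[b, a] += rates[e.forward]
        K[a, b] += rates[e.reverse]
    K[np.diag_indices(n)] -= K.sum(axis=0)
    return K


def equilibrium_distribution(scheme: KineticScheme, rates: RateSet) -> StateOccupancy:
    K = generator_matrix(scheme, rates)
    ns = scipy.linalg.null_space(K)
    if ns.shape[1] != 1:
        raise SchemeError(
            "generator null space is not one-dimensional; the network is "
            "effectively disconnected for these rates"
        )
    p = ns[:, 0]
    p = p * np.sign(p.sum())
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return StateOccupancy(states=scheme.states, probabilities=p)


def rate_matrix_spectrum(scheme: KineticScheme, rates: RateSet) -> SpectrumResult:
    """Equilibrium occupancy plus the relaxation eigenvalue spectrum.

    Eigenvalues are sorted by ascending magnitude of the real part; the
    first is the zero mode.  All nonzero eigenvalues have nonpositive real
    parts for a valid generator.
    """
    K = generator_matrix(scheme, rates)
    occ = equilibrium_distribution(scheme, rates)
    ev = np.linalg.eigvals(K)
    ev = ev[np.argsort(np.abs(ev.real))]
    if np.max(ev.real) > 1e-6 * max(1.0, np.abs(ev.real).max()):
        raise SchemeError("generator has a positive eigenvalue; invalid rates")
    return SpectrumResult(occupancy=occ, eigenvalues=ev, generator=K)


def _propagator_terms(K: np.ndarray, cond_limit: float = 1e12):
    """Eigen-decomposition K = V diag(lam) V^-1, or None if ill-conditioned."""
    lam, V = np.linalg.eig(K)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return None
    if not np.isfinite(cond) or cond > cond_limit:
        return None
    Vinv = np.linalg.inv(V)
    return lam, V, Vinv


def correlation_mode_amplitudes(
    scheme: KineticScheme, rates: RateSet
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral representation of the correlation-mode decay.

    Returns ``(lambdas, amps)`` such that
    y(t) = sum_i amps_i * exp(lambdas_i * t), with the zero mode already
    removed (it cancels against the -1 baseline).  Used both by
    :func:`simulate_dynamic_component` and by the correlator-response
    oracle in :mod:`petfcs.synthetic`.
    """
    K = generator_matrix(scheme, rates)
    p = equilibrium_distribution(scheme, rates).probabilities
    q = scheme.brightness_vector
    mean_b = float(q @ p)
    if mean_b <= 0:
        raise SchemeError("zero equilibrium brightness")
    terms = _propagator_terms(K)
    if terms is None:
        raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
    lam, V, Vinv = terms
    # y(t) + 1 = q^T exp(Kt) diag(p) q / mean_b^2
    amps = (q @ V) * (Vinv @ (p * q)) / mean_b**2
    keep = np.abs(lam) > 1e-12 * max(1.0, np.abs(lam).max())
    return lam[keep], amps[keep]


def simulate_dynamic_component(
    scheme: KineticScheme,
    rates: RateSet,
    times: np.ndarray,
    mode: str = "correlation",
    amplitudes: dict[str, float] | None = None,
) -> DecayCurve:
    """Predicted dynamic ACF component of the network.

    correlation mode
        y(t) = q^T exp(Kt) diag(p) q / (q.p)^2 - 1 with q the brightness
        vector and p the equilibrium distribution: the normalized
        fluorescence fluctuation autocorrelation of the Markov process.
    amplitude-fit mode
        y(t) = sum_s a_s (x_s(t) - x_s(inf)) with x(0) the equilibrium
        conditioned on fluorescent states (the photon-weighted initial
        condition) and a_s free species amplitude coefficients
        (default: the brightness flags, which reproduces correlation mode
        up to normalization for two-state networks).

    Both modes decay to 0 as t -> inf.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if mode == "correlation":
        if amplitudes is not None:
            raise ValueError("amplitudes are not accepted in correlation mode")
        try:
            lam, amps = correlation_mode_amplitudes(scheme, rates)
            y = np.real(amps[None, :] @ np.exp(np.outer(lam, times))).ravel()
        except np.linalg.LinAlgError:
            # scaling-and-squaring fallback for ill-conditioned eigenbases
            K = generator_matrix(scheme, rates)
            p = equilibrium_distribution(scheme, rates).probabilities
            q = scheme.brightness_vector
            mean_b = float(q @ p)
            y = np.array(
                [q @ scipy.linalg.expm(K * t) @ (p * q) / mean_b**2 - 1.0 for t in times]
            )
        return DecayCurve(times=times, values=y, mode=mode)
    if mode == "amplitude-fit":
        K = generator_matrix(scheme, rates)
        p = equilibrium_distribution(scheme, rates).probabilities
        q = scheme.brightness_vector
        a = (
            q.copy()
            if amplitudes is None
            else np.array([amplitudes.get(s, 0.0) for s in scheme.states])
        )
        x0 = p * q
        x0 = x0 / x0.sum()
        terms = _propagator_terms(K)
        if terms is not None:
            lam, V, Vinv = terms
            coefs = (a @ V) * (Vinv @ x0)
            keep = np.abs(lam) > 1e-12 * max(1.0, np.abs(lam).max())
            y = np.real(coefs[keep][None, :] @ np.exp(np.outer(lam[keep], times))).ravel()
        else:  # pragma: no cover - degenerate spectra
            y = np.array([a @ (scipy.linalg.expm(K * t) @ x0 - p) for t in times])
        amap = {s: float(v) for s, v in zip(scheme.states, a)}
        return DecayCurve(times=times, values=y, mode=mode, amplitudes=amap)
    raise ValueError(f"unknown mode {mode!r}")


def without_trp_quenching(scheme: KineticScheme, rates: RateSet) -> RateSet:
    """Rates for a W6F-style construct: Trp-quenching on-rates set to 0."""
    values = dict(rates.values)
    for name in scheme.trp_on_rates:
        if name in values:
            values[name] = 0.0
    return RateSet(values=values, bimolecular=rates.bimolecular & frozenset())
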