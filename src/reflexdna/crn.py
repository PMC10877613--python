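"""Mass-action chemical reaction networks with timed input dosing.

This module is the simulation substrate for the conditioned-reflex DNA
strand-displacement circuits: a generic representation of a well-mixed
reaction network (reversible bimolecular exchanges, irreversible
unimolecular decays), deterministic ODE integration between instantaneous
dose events, conservation-law extraction, and per-window response metrics.

Units are fixed globally: concentrations in nM, time in seconds,
bimolecular rate constants in 1/(nM*s), unimolecular in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesSpec",
    "Reaction",
    "ReactionNetwork",
    "DoseEvent",
    "DoseSchedule",
    "SolverConfig",
    "Trajectory",
    "WindowMetrics",
    "ConservationGroup",
    "ConfigurationError",
    "SolverError",
    "mass_action_rhs",
    "simulate",
    "conservation_groups",
    "window_metrics",
]


class ConfigurationError(ValueError):
    """A network, schedule or parameter set violates its invariants."""


class SolverError(RuntimeError):
    """The ODE integrator failed; the message names the failing interval."""


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species: a single- or double-stranded DNA complex.

    Parameters
    ----------
    name
        Unique identifier within a network (e.g. ``"M2"``).
    initial_concentration
        Concentration at t = 0 in nM; must be non-negative.
    strandedness
        ``"single"`` or ``"double"``; informational.
    role
        Free-text functional tag (input / excitation / memory gate /
        reservoir / reward / waiting / output / threshold-gate component).
    """

    name: str
    initial_concentration: float = 0.0
    strandedness: str = "single"
    role: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("species name must be non-empty")
        if self.initial_concentration < 0:
            raise ConfigurationError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )
        if self.strandedness not in ("single", "double"):
            raise ConfigurationError(
                f"species {self.name!r}: strandedness must be 'single' or "
                f"'double', got {self.strandedness!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction with 1-2 reactants and 0-2 products.

    A reversible strand-displacement exchange is written ``A + B <=> C + D``
    with forward rate ``k_forward`` (1/(nM*s)) and backward rate
    ``k_backward``.  An irreversible degradation is written ``A -> (waste)``
    with an empty product list, unimolecular ``k_forward`` (1/s) and
    ``k_backward = 0``; the waste is implicit and not tracked.

    ``mode_rates`` optionally overrides ``(k_forward, k_backward)`` per
    light-irradiation mode (``"BL"`` / ``"UV"``), used by the
    photoswitchable threshold gate.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_forward: float
    k_backward: float = 0.0
    label: str = ""
    mode_rates: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise ConfigurationError(
                f"reaction {self.label!r}: needs 1-2 reactants, got "
                f"{len(self.reactants)}"
            )
        if len(self.products) > 2:
            raise ConfigurationError(
                f"reaction {self.label!r}: needs 0-2 products"
            )
        if self.k_forward < 0 or self.k_backward < 0:
            raise ConfigurationError(
                f"reaction {self.label!r}: rate constants must be >= 0"
            )
        if not self.products and self.k_backward != 0:
            raise ConfigurationError(
                f"reaction {self.label!r}: a degradation (no products) "
                "must be irreversible (k_backward = 0)"
            )
        if self.mode_rates is not None:
            object.__setattr__(self, "mode_rates", dict(self.mode_rates))

    @property
    def is_degradation(self) -> bool:
        return not self.products

    def rates(self, mode: str | None = None) -> tuple[float, float]:
        """Effective (k_forward, k_backward) under an irradiation mode."""
        if mode is not None and self.mode_rates and mode in self.mode_rates:
            return self.mode_rates[mode]
        return (self.k_forward, self.k_backward)


class ReactionNetwork:
    """A validated species roster plus mass-action reaction list.

    The network compiles itself to index arrays once, so the ODE
    right-hand side is a handful of vectorized numpy operations.
    """

    def __init__(
        self,
        species: Sequence[SpeciesSpec],
        reactions: Sequence[Reaction],
    ) -> None:
        self.species = list(species)
        self.reactions = list(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate species names: {dupes}")
        self._index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in self._index:
                    raise ConfigurationError(
                        f"reaction {rxn.label!r} references unknown species "
                        f"{name!r}"
                    )
        self._compiled: dict[str | None, tuple] = {}

    # -- introspection -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array(
            [s.initial_concentration for s in self.species], dtype=float
        )

    def stoichiometric_matrix(
        self, include_degradation: bool = True
    ) -> np.ndarray:
        """Net stoichiometry, species x reactions (+1 product, -1 reactant)."""
        cols = [
            r for r in self.reactions
            if include_degradation or not r.is_degradation
        ]
        S = np.zeros((self.n_species, len(cols)))
        for j, rxn in enumerate(cols):
            for name in rxn.reactants:
                S[self._index[name], j] -= 1
            for name in rxn.products:
                S[self._index[name], j] += 1
        return S

    # -- compiled kinetics ---------------------------------------------
    def _compile(self, mode: str | None):
        """Index arrays for the vectorized rhs; cached per mode.

        Missing reactant/product slots point at a virtual species with
        constant concentration 1.0 (index n); derivative contributions
        scattered there are discarded.
        """
        if mode in self._compiled:
            return self._compiled[mode]
        n = self.n_species
        R = len(self.reactions)
        ri = np.full((R, 2), n, dtype=np.intp)
        pi = np.full((R, 2), n, dtype=np.intp)
        kf = np.zeros(R)
        kb = np.zeros(R)
        for j, rxn in enumerate(self.reactions):
            for slot, name in enumerate(rxn.reactants):
                ri[j, slot] = self._index[name]
            for slot, name in enumerate(rxn.products):
                pi[j, slot] = self._index[name]
            kf[j], kb[j] = rxn.rates(mode)
        self._compiled[mode] = (ri, pi, kf, kb)
        return self._compiled[mode]

    def rhs(self, state: np.ndarray, mode: str | None = None) -> np.ndarray:
        """Time derivative (nM/s) of the concentration vector."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise ConfigurationError(
                f"state length {state.shape} does not match species count "
                f"{self.n_species}"
            )
        if not np.all(np.isfinite(state)):
            raise ConfigurationError("state contains non-finite entries")
        ri, pi, kf, kb = self._compile(mode)
        xe = np.append(state, 1.0)
        flux = kf * xe[ri[:, 0]] * xe[ri[:, 1]] - kb * xe[pi[:, 0]] * xe[pi[:, 1]]
        dxe = np.zeros(self.n_species + 1)
        np.add.at(dxe, ri[:, 0], -flux)
        np.add.at(dxe, ri[:, 1], -flux)
        np.add.at(dxe, pi[:, 0], flux)
        np.add.at(dxe, pi[:, 1], flux)
        return dxe[:-1]


def mass_action_rhs(
    network: ReactionNetwork, state: np.ndarray, mode: str | None = None
) -> np.ndarray:
    """Mass-action derivative vector: for each ``A + B <=> C + D`` the flux
    ``k_f [A][B] - k_b [C][D]`` is subtracted from reactants and added to
    products; unimolecular flux is ``k_f [A]``."""
    return network.rhs(state, mode=mode)


@dataclass(frozen=True)
class DoseEvent:
    """Instantaneous addition of ``amount`` nM of ``species`` at ``time`` s."""

    time: float
    species: str
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ConfigurationError("dose time must be >= 0")
        if self.amount <= 0:
            raise ConfigurationError("dose amount must be > 0")


@dataclass
class DoseSchedule:
    """Timed input administrations plus the simulation horizon (s)."""

    events: list[DoseEvent]
    horizon: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        last = max((e.time for e in self.events), default=0.0)
        if self.horizon <= last:
            raise ConfigurationError(
                f"horizon {self.horizon} must exceed last event time {last}"
            )

    @property
    def event_times(self) -> list[float]:
        return sorted({e.time for e in self.events})


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-capable integration settings.

    Defaults: relative tolerance 1e-8, absolute tolerance 1e-10 nM, output
    grid at one point per 10 s (dense enough for peak extraction).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    max_grid_dt: float = 10.0


@dataclass
class Trajectory:
    """Time grid x species concentration matrix, with dose-time markers.

    ``concentrations`` holds the raw solver output (which may dip a hair
    below zero within tolerance); :meth:`species` returns values clipped
    at zero, which is what all metric extraction uses.
    """

    times: np.ndarray
    concentrations: np.ndarray
    species_names: list[str]
    event_markers: list[float] = field(default_factory=list)

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    def species(self, name: str) -> np.ndarray:
        """Concentration time series of one species, clipped at 0 nM."""
        return np.clip(self.concentrations[:, self.index(name)], 0.0, None)

    def to_frame(self):
        """As a pandas DataFrame with a ``time_s`` column plus one per species."""
        import pandas as pd

        df = pd.DataFrame(self.concentrations, columns=self.species_names)
        df.insert(0, "time_s", self.times)
        return df


def simulate(
    network: ReactionNetwork,
    schedule: DoseSchedule,
    solver: SolverConfig | None = None,
    mode_changes: Sequence[tuple[float, str]] = (),
) -> Trajectory:
    """Integrate the network ODEs under a dose schedule.

    Integration proceeds piecewise between breakpoints (dose times and
    irradiation-mode switches).  At each dose time the dosed amounts are
    added to the state instantaneously and integration restarts; the
    trajectory sample at a dose time is the post-dose state.

    ``mode_changes`` is a sorted sequence of ``(time, mode)`` pairs; from
    each time onward, reactions carrying ``mode_rates`` use the rates of
    that mode.
    """
    cfg = solver or SolverConfig()
    doses: dict[float, list[DoseEvent]] = {}
    for ev in schedule.events:
        network.index(ev.species)  # validate name early
        doses.setdefault(ev.time, []).append(ev)
    mode_changes = sorted(mode_changes, key=lambda m: m[0])

    breakpoints = sorted(
        {0.0, schedule.horizon}
        | set(doses)
        | {t for t, _ in mode_changes if 0.0 <= t < schedule.horizon}
    )

    def mode_at(t: float) -> str | None:
        current: str | None = None
        for mt, m in mode_changes:
            if mt <= t:
                current = m
        return current

    x = network.initial_state()
    all_t: list[np.ndarray] = []
    all_x: list[np.ndarray] = []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        for ev in doses.get(a, ()):
            x[network.index(ev.species)] += ev.amount
        mode = mode_at(a)
        n_pts = max(2, int(np.ceil((b - a) / cfg.max_grid_dt)) + 1)
        t_eval = np.linspace(a, b, n_pts)
        sol = solve_ivp(
            lambda t, y: network.rhs(y, mode=mode),
            (a, b),
            x,
            method=cfg.method,
            rtol=cfg.rtol,
            atol=cfg.atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed on [{a:g}, {b:g}] s: {sol.message}"
            )
        x = sol.y[:, -1].copy()
        keep = slice(None) if b == breakpoints[-1] else slice(None, -1)
        all_t.append(sol.t[keep])
        all_x.append(sol.y.T[keep])
    return Trajectory(
        times=np.concatenate(all_t),
        concentrations=np.vstack(all_x),
        species_names=network.species_names,
        event_markers=sorted(doses),
    )


@dataclass(frozen=True)
class WindowMetrics:
    peak: float
    peak_time: float
    end_value: float


def window_metrics(
    traj: Trajectory, species: str, window: tuple[float, float]
) -> WindowMetrics:
    """Peak, peak time and end value of one species over a time window.

    The window is half-open ``[t_start, t_end)`` except that the final
    trajectory sample is included when ``t_end`` reaches it; the end value
    (the steady-state proxy) is the last sample before ``t_end``, i.e. the
    reading just before the next dose.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError(f"empty window ({t0}, {t1})")
    t = traj.times
    mask = (t >= t0) & ((t < t1) | (t1 >= t[-1]) & (t <= t1))
    if not mask.any():
        raise ConfigurationError(
            f"window ({t0}, {t1}) contains no trajectory samples"
        )
    y = traj.species(species)[mask]
    tw = t[mask]
    i = int(np.argmax(y))
    return WindowMetrics(peak=float(y[i]), peak_time=float(tw[i]),
                         end_value=float(y[-1]))


@dataclass(frozen=True)
class ConservationGroup:
    """A weighted sum of species concentrations invariant along trajectories.

    ``broken_by_degradation`` is True for groups conserved by the reversible
    strand-displacement reactions but drained by an input-degradation
    reaction (e.g. any group containing a free input strand).
    """

    weights: dict[str, int]
    total: float
    broken_by_degradation: bool

    def value(self, traj_or_state, network: ReactionNetwork | None = None):
        """Evaluate the weighted sum on a Trajectory or a state vector."""
        if isinstance(traj_or_state, Trajectory):
            out = np.zeros_like(traj_or_state.times)
            for name, w in self.weights.items():
                out = out + w * traj_or_state.concentrations[
                    :, traj_or_state.index(name)
                ]
            return out
        if network is None:
            raise ConfigurationError("network required for a raw state vector")
        return float(
            sum(w * traj_or_state[network.index(n)]
                for n, w in self.weights.items())
        )


def _integer_nullspace(S: np.ndarray) -> list[np.ndarray]:
    """Left null space of S (w such that w @ S = 0), as integer vectors."""
    M = sympy.Matrix(S.astype(int)).T
    basis = M.nullspace()
    out = []
    for v in basis:
        denoms = [sympy.Rational(x).q for x in v]
        scale = sympy.ilcm(*denoms) if len(denoms) > 1 else (denoms[0] if denoms else 1)
        w = np.array([int(x * scale) for x in v], dtype=int)
        g = int(np.gcd.reduce(np.abs(w[w != 0]))) if np.any(w) else 1
        w = w // g
        nz = w[w != 0]
        if len(nz) and nz[0] < 0:
            w = -w
        out.append(w)
    return out


def conservation_groups(network: ReactionNetwork) -> list[ConservationGroup]:
    """Conservation laws of the network.

    Groups conserved under *all* reactions (left null space of the full
    stoichiometric matrix) are returned first with
    ``broken_by_degradation=False``; the basis is then completed to the
    null space of the degradation-free matrix, and the completion vectors
    -- invariant under the reversible exchanges but drained by degradation
    -- are flagged ``broken_by_degradation=True``.
    """
    S_full = network.stoichiometric_matrix(include_degradation=True)
    S_rev = network.stoichiometric_matrix(include_degradation=False)
    unbroken = _integer_nullspace(S_full)
    rev_space = _integer_nullspace(S_rev)

    x0 = network.initial_state()
    names = network.species_names
    groups = [
        ConservationGroup(
            weights={n: int(w) for n, w in zip(names, vec) if w != 0},
            total=float(vec @ x0),
            broken_by_degradation=False,
        )
        for vec in unbroken
    ]
    # complete to the reversible-only null space
    stack = [v.astype(float) for v in unbroken]
    for vec in rev_space:
        cand = stack + [vec.astype(float)]
        if np.linalg.matrix_rank(np.array(cand)) > len(stack):
            stack = cand
            groups.append(
                ConservationGroup(
                    weights={n: int(w) for n, w in zip(names, vec) if w != 0},
                    total=float(vec @ x0),
                    broken_by_degradation=True,
                )
            )
    return groups
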