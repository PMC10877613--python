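"""Parameter estimation for the conditioned-reflex circuit.

The circuit's free parameters are its initial gate concentrations, the
two degradation rates, and the strand-displacement rate constants, which
are set by the toehold lengths (3-6 nt) of the four toehold domains.  The
design objective is a cost over four response statistics:

- ``J_pk^(1,2)``, ``J_ss^(1,2)``: peak and steady-state output of a
  simultaneous I1+I2 presentation at the prelearning condition;
- ``J_pk^(2)``, ``J_ss^(2)``: peak and steady-state output of an I2
  presentation at the postlearning condition (one training presentation
  earlier).

The default cost ``J = -J_pk^(2) + alpha (J_ss^(1,2) + J_ss^(2))``
maximizes the conditioned response while penalizing non-renewal (output
that fails to decay between presentations).  A small seeded genetic
algorithm searches concentrations, degradation rates and integer toehold
lengths; rates enter through a configurable length -> rate lookup table
(only the 5-nt entry, 5.32e-4 1/(nM*s), is anchored by measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .crn import ConfigurationError, SolverConfig
from .circuit import CircuitParams, InputPattern, run_pattern

__all__ = [
    "ResponseStats",
    "CostSpec",
    "GASettings",
    "GAResult",
    "EstimationProblem",
    "DEFAULT_TOEHOLD_RATES",
    "response_statistics",
    "evaluate_cost",
    "minimize_ga",
    "run_ga",
    "local_sensitivity",
    "round_to_one_significant",
]

#: Toehold length (nt) -> strand-displacement rate constant (1/(nM*s)).
#: Only the 5-nt entry is an anchored measurement; the others are
#: order-of-magnitude placeholders (rates rise steeply with toehold length
#: before saturating) used during GA exploration only.
DEFAULT_TOEHOLD_RATES: Mapping[int, float] = {
    3: 5.0e-6, 4: 5.0e-5, 5: 5.32e-4, 6: 1.0e-3,
}


@dataclass(frozen=True)
class ResponseStats:
    """The four response statistics the design cost is built from (nM)."""

    j_pk_12: float
    j_ss_12: float
    j_pk_2: float
    j_ss_2: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.j_pk_12, self.j_ss_12, self.j_pk_2, self.j_ss_2)


def response_statistics(
    params: CircuitParams,
    interval: float = 18000.0,
    solver: SolverConfig | None = None,
) -> ResponseStats:
    """Simulate the two probe protocols and read the four statistics.

    Prelearning: a single simultaneous FB presentation; peak and
    window-end value of O.  Postlearning: pattern FB-B (one training
    presentation, then the conditioned probe); peak and window-end value
    of O after the B presentation.
    """
    pre = InputPattern(("FB",), interval=interval, post_window=interval)
    _, pre_report = run_pattern(params, pre, solver=solver)
    post = InputPattern(("FB", "B"), interval=interval, post_window=interval)
    _, post_report = run_pattern(params, post, solver=solver)
    e12 = pre_report.per_event[0]
    e2 = post_report.per_event[1]
    return ResponseStats(
        j_pk_12=e12.output_peak, j_ss_12=e12.output_end,
        j_pk_2=e2.output_peak, j_ss_2=e2.output_end,
    )


@dataclass(frozen=True)
class CostSpec:
    """Linear weighting of the four response statistics.

    The default weights realize ``J = -J_pk^(2) + alpha (J_ss^(1,2) +
    J_ss^(2))`` with alpha = 1; ``form`` may be replaced by any callable
    ``stats -> float`` for alternative functional forms.
    """

    w_pk_12: float = 0.0
    w_ss_12: float = 1.0
    w_pk_2: float = -1.0
    w_ss_2: float = 1.0
    form: Callable[[ResponseStats], float] | None = None

    def __post_init__(self) -> None:
        for w in (self.w_pk_12, self.w_ss_12, self.w_pk_2, self.w_ss_2):
            if not np.isfinite(w):
                raise ConfigurationError("cost weights must be finite")


def evaluate_cost(spec: CostSpec, stats: ResponseStats) -> float:
    """Scalar design cost of a parameter set's response statistics."""
    if not all(np.isfinite(stats.as_tuple())):
        raise ConfigurationError("response statistics must be finite")
    if spec.form is not None:
        return float(spec.form(stats))
    return float(
        spec.w_pk_12 * stats.j_pk_12
        + spec.w_ss_12 * stats.j_ss_12
        + spec.w_pk_2 * stats.j_pk_2
        + spec.w_ss_2 * stats.j_ss_2
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GASettings:
    population: int = 40
    generations: int = 30
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_scale: float = 0.2  # gaussian sd, as a fraction of the range
    elite: int = 1


@dataclass
class GAResult:
    x_real: np.ndarray
    x_int: np.ndarray
    cost: float
    history: np.ndarray  # best cost per generation


def minimize_ga(
    objective: Callable[[np.ndarray, np.ndarray], float],
    real_bounds: Sequence[tuple[float, float]],
    int_bounds: Sequence[tuple[int, int]] = (),
    settings: GASettings | None = None,
    seed: int = 0,
) -> GAResult:
    """Minimize a mixed real/integer objective with a seeded GA.

    ``objective(x_real, x_int)`` is evaluated on real genes within
    ``real_bounds`` and integer genes within inclusive ``int_bounds``.
    Tournament selection, blend (BLX) crossover on reals, uniform
    crossover and random-reset mutation on integers, elitism, and a fixed
    numpy PRNG seed make runs bit-reproducible.
    """
    cfg = settings or GASettings()
    rng = np.random.default_rng(seed)
    rlo = np.array([b[0] for b in real_bounds], dtype=float)
    rhi = np.array([b[1] for b in real_bounds], dtype=float)
    ilo = np.array([b[0] for b in int_bounds], dtype=int)
    ihi = np.array([b[1] for b in int_bounds], dtype=int)
    if np.any(rhi < rlo) or np.any(ihi < ilo):
        raise ConfigurationError("infeasible bounds: upper < lower")
    nr, ni = len(rlo), len(ilo)
    span = rhi - rlo

    pop_r = rng.uniform(rlo, rhi, size=(cfg.population, nr)) if nr else \
        np.zeros((cfg.population, 0))
    pop_i = rng.integers(ilo, ihi + 1, size=(cfg.population, ni)) if ni else \
        np.zeros((cfg.population, 0), dtype=int)

    def evaluate(pr, pi):
        return np.array([objective(r, i) for r, i in zip(pr, pi)])

    costs = evaluate(pop_r, pop_i)
    history = []
    for _ in range(cfg.generations):
        order = np.argsort(costs)
        history.append(costs[order[0]])
        elites_r = pop_r[order[: cfg.elite]].copy()
        elites_i = pop_i[order[: cfg.elite]].copy()

        def tournament_pick():
            idx = rng.integers(0, cfg.population, size=cfg.tournament)
            return idx[np.argmin(costs[idx])]

        children_r, children_i = [], []
        while len(children_r) < cfg.population - cfg.elite:
            a, b = tournament_pick(), tournament_pick()
            ra, rb = pop_r[a].copy(), pop_r[b].copy()
            ia, ib = pop_i[a].copy(), pop_i[b].copy()
            if nr and rng.random() < cfg.crossover_rate:
                gamma = rng.uniform(-0.5, 1.5, size=nr)  # BLX-alpha 0.5
                ra = np.clip(gamma * ra + (1 - gamma) * rb, rlo, rhi)
            if ni and rng.random() < cfg.crossover_rate:
                swap = rng.random(ni) < 0.5
                ia = np.where(swap, ib, ia)
            if nr:
                mut = rng.random(nr) < cfg.mutation_rate
                ra = np.clip(
                    ra + mut * rng.normal(0, cfg.mutation_scale, nr) * span,
                    rlo, rhi,
                )
            if ni:
                mut = rng.random(ni) < cfg.mutation_rate
                resets = rng.integers(ilo, ihi + 1, size=ni)
                ia = np.where(mut, resets, ia)
            children_r.append(ra)
            children_i.append(ia)
        pop_r = np.vstack([elites_r, children_r]) if nr else pop_r
        pop_i = (np.vstack([elites_i, children_i]).astype(int)
                 if ni else pop_i)
        costs = np.concatenate(
            [costs[order[: cfg.elite]],
             evaluate(pop_r[cfg.elite:], pop_i[cfg.elite:])]
        )
    best = int(np.argmin(costs))
    history.append(costs[best])
    return GAResult(
        x_real=pop_r[best].copy(),
        x_int=pop_i[best].copy(),
        cost=float(costs[best]),
        history=np.array(history),
    )


#: Adjustable initial-concentration species, in genome order.
CONC_SPECIES = ("M1", "M2p", "S", "R2", "R1")

#: Which toehold domain each strand-displacement reaction's rate follows.
#: The structural assignment of the four toehold domains (t1, t2, ta, tb)
#: to the five reactions; r4 and r5 share the I2-side toehold.
TOEHOLD_ASSIGNMENT: Mapping[str, str] = {
    "r1": "t1", "r2": "ta", "r3": "tb", "r4": "t2", "r5": "t2",
}

TOEHOLD_NAMES = ("t1", "t2", "ta", "tb")


@dataclass
class EstimationProblem:
    """GA search space for the circuit's design parameters.

    Decision variables: the five nonzero initial concentrations (nM), the
    two degradation rates (1/s, log-uniform bounds), and four integer
    toehold lengths in 3..6 indexing ``rate_table``.  The shared circuit
    rate constant is taken from the toehold gene named by
    ``rate_toehold`` (default ``t1``; with the default table and length 5
    this reproduces the measured 5.32e-4).
    """

    conc_bounds: tuple[float, float] = (0.0, 200.0)
    kd_bounds: tuple[float, float] = (1e-4, 1.0)
    toehold_range: tuple[int, int] = (3, 6)
    rate_table: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TOEHOLD_RATES)
    )
    rate_toehold: str = "t1"
    cost: CostSpec = field(default_factory=CostSpec)
    settings: GASettings = field(default_factory=GASettings)
    seed: int = 0
    solver: SolverConfig | None = None

    def __post_init__(self) -> None:
        lo, hi = self.toehold_range
        if not (3 <= lo <= hi <= 6):
            raise ConfigurationError("toehold lengths must lie in 3..6")
        for length in range(lo, hi + 1):
            if length not in self.rate_table:
                raise ConfigurationError(
                    f"rate_table missing toehold length {length}"
                )
            if self.rate_table[length] <= 0:
                raise ConfigurationError("rates must be > 0")
        if self.rate_toehold not in TOEHOLD_NAMES:
            raise ConfigurationError(
                f"rate_toehold must be one of {TOEHOLD_NAMES}"
            )

    def decode(self, x_real: np.ndarray, x_int: np.ndarray) -> CircuitParams:
        """Genome -> CircuitParams (kd genes are log10-scaled)."""
        init = {s: float(c) for s, c in zip(CONC_SPECIES, x_real[:5])}
        kd1, kd2 = (10.0 ** x_real[5], 10.0 ** x_real[6])
        toeholds = {n: int(v) for n, v in zip(TOEHOLD_NAMES, x_int)}
        k = self.rate_table[toeholds[self.rate_toehold]]
        return CircuitParams(
            k_forward=k, k_backward=k, k_d1=kd1, k_d2=kd2, init=init
        )

    def real_bounds(self) -> list[tuple[float, float]]:
        lo, hi = self.kd_bounds
        return [self.conc_bounds] * 5 + [(np.log10(lo), np.log10(hi))] * 2

    def int_bounds(self) -> list[tuple[int, int]]:
        return [self.toehold_range] * 4


@dataclass
class EstimationResult:
    params: CircuitParams
    toehold_lengths: dict[str, int]
    cost: float
    history: np.ndarray


def run_ga(problem: EstimationProblem) -> EstimationResult:
    """Search the design space; seeded runs are bit-reproducible."""

    def objective(x_real: np.ndarray, x_int: np.ndarray) -> float:
        params = problem.decode(x_real, x_int)
        stats = response_statistics(params, solver=problem.solver)
        return evaluate_cost(problem.cost, stats)

    res = minimize_ga(
        objective,
        problem.real_bounds(),
        problem.int_bounds(),
        settings=problem.settings,
        seed=problem.seed,
    )
    return EstimationResult(
        params=problem.decode(res.x_real, res.x_int),
        toehold_lengths={n: int(v) for n, v in zip(TOEHOLD_NAMES, res.x_int)},
        cost=res.cost,
        history=res.history,
    )


def round_to_one_significant(x: float) -> float:
    """Round a reported estimate to one significant digit."""
    if x == 0:
        return 0.0
    exp = np.floor(np.log10(abs(x)))
    return float(np.round(x / 10 ** exp) * 10 ** exp)


# ---------------------------------------------------------------------------
# Local sensitivity
# ---------------------------------------------------------------------------

_METRIC_READERS: dict[str, Callable[[ResponseStats], float]] = {
    "peak_12": lambda s: s.j_pk_12,
    "ss_12": lambda s: s.j_ss_12,
    "peak_2": lambda s: s.j_pk_2,
    "ss_2": lambda s: s.j_ss_2,
}


@dataclass(frozen=True)
class SensitivityCoefficient:
    value: float
    normalized: bool  # True: d log(metric) / d log(param); False: d metric / d param


def _perturb(params: CircuitParams, name: str, factor: float) -> CircuitParams:
    if name in params.init:
        init = dict(params.init)
        init[name] = init[name] * factor
        return replace(params, init=init)
    return replace(params, **{name: getattr(params, name) * factor})


def local_sensitivity(
    params: CircuitParams,
    metric: str | Callable[[CircuitParams], float] = "peak_2",
    rel_step: float = 0.05,
    solver: SolverConfig | None = None,
) -> dict[str, SensitivityCoefficient]:
    """Central finite-difference sensitivities of a response statistic.

    For each rate constant and nonzero initial concentration p, the
    normalized coefficient d log(metric) / d log(p) is computed with a
    relative step of ``rel_step``.  Where the baseline metric is zero the
    coefficient is reported unnormalized (d metric / d p).
    """
    if not 0 < rel_step < 0.5:
        raise ConfigurationError("rel_step must lie in (0, 0.5)")
    if isinstance(metric, str):
        if metric not in _METRIC_READERS:
            raise ConfigurationError(
                f"unknown metric {metric!r}; options: "
                f"{sorted(_METRIC_READERS)}"
            )
        reader = _METRIC_READERS[metric]

        def metric_fn(p: CircuitParams) -> float:
            return reader(response_statistics(p, solver=solver))
    else:
        metric_fn = metric

    base = metric_fn(params)
    names = ["k_forward", "k_backward", "k_d1", "k_d2"] + [
        n for n, c in params.init.items() if c > 0
    ]
    out: dict[str, SensitivityCoefficient] = {}
    for name in names:
        p0 = (params.init[name] if name in params.init
              else getattr(params, name))
        if p0 == 0:
            out[name] = SensitivityCoefficient(0.0, normalized=False)
            continue
        up = metric_fn(_perturb(params, name, 1 + rel_step))
        dn = metric_fn(_perturb(params, name, 1 - rel_step))
        dmetric_dp = (up - dn) / (2 * rel_step * p0)
        if base != 0:
            out[name] = SensitivityCoefficient(
                dmetric_dp * p0 / base, normalized=True
            )
        else:
            out[name] = SensitivityCoefficient(dmetric_dp, normalized=False)
    return out
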