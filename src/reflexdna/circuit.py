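"""The two-input conditioned-reflex circuit and its learning experiments.

The circuit is a molecular implementation of Pavlovian conditioning built
from five reversible toehold-mediated strand-displacement reactions plus
two input-degradation reactions.  Input I1 ("feed", unconditioned
stimulus) always elicits the output strand O; input I2 ("bell", neutral
stimulus) does not until a *simultaneous* I1+I2 presentation charges the
memory gate M2 through the coincidence of the excitation strand Y2
(produced downstream of the output) with the waiting strand W2 (produced
by I2 on the pseudomemory gate M2p).  Afterwards I2 alone elicits output:
the circuit's logic has plastically switched from YES to OR.  Repeated
unpaired I2 presentations drain M2 again (forgetting), and input
degradation renews every other species between presentations.

Input histories are written as pattern strings over tokens F (dose I1),
B (dose I2) and FB (dose both simultaneously), e.g. ``"B-FB-B"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .crn import (
    ConfigurationError,
    DoseEvent,
    DoseSchedule,
    Reaction,
    ReactionNetwork,
    SolverConfig,
    SpeciesSpec,
    Trajectory,
    simulate,
    window_metrics,
)

__all__ = [
    "CircuitParams",
    "InputPattern",
    "EventMetrics",
    "MetricsReport",
    "build_two_input_circuit",
    "parse_pattern",
    "run_pattern",
    "learning_efficiency",
    "forgetting_experiment",
    "synchronization_experiment",
    "SyncPoint",
]

#: Default initial concentrations (nM): the estimated optimum.
DEFAULT_INIT: Mapping[str, float] = {
    "M1": 100.0, "M2p": 100.0, "S": 100.0, "R2": 100.0, "R1": 50.0,
}

#: Shared strand-displacement rate constant, 1/(nM*s), for a 5-nt toehold.
DEFAULT_K = 5.32e-4

#: Default inter-event interval: 5 hours, in seconds.
DEFAULT_INTERVAL = 18000.0


@dataclass(frozen=True)
class CircuitParams:
    """Rate constants and initial concentrations of the two-input circuit.

    All five strand-displacement reactions share one forward and one
    backward rate constant by default (``5.32e-4`` 1/(nM*s), the value for
    the optimal 5-nt toeholds); the two degradation reactions default to
    ``0.01`` 1/s.  ``init`` lists only the nonzero initial concentrations;
    every unlisted species starts at 0 nM.
    """

    k_forward: float = DEFAULT_K
    k_backward: float = DEFAULT_K
    k_d1: float = 0.01
    k_d2: float = 0.01
    init: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INIT))
    dose_amount: float = 100.0

    def __post_init__(self) -> None:
        for k in (self.k_forward, self.k_backward, self.k_d1, self.k_d2):
            if k < 0:
                raise ConfigurationError("rate constants must be >= 0")
        for name, c in self.init.items():
            if c < 0:
                raise ConfigurationError(
                    f"initial concentration of {name!r} must be >= 0"
                )
        if self.dose_amount < 0:
            raise ConfigurationError("dose amount must be >= 0")

    def high_capacity(self) -> "CircuitParams":
        """The doubled-gate / 10x-degradation variant: gate initial
        concentrations raised to 200 nM (R1 kept at 50 nM), kd = 0.1 1/s."""
        init = {"M1": 200.0, "M2p": 200.0, "S": 200.0, "R2": 200.0, "R1": 50.0}
        return replace(self, init=init, k_d1=self.k_d1 * 10,
                       k_d2=self.k_d2 * 10)


#: Species roster of the two-input circuit (singles first, then duplexes).
TWO_INPUT_SPECIES: tuple[tuple[str, str, str], ...] = (
    ("I1", "single", "input (unconditioned stimulus)"),
    ("I2", "single", "input (neutral stimulus)"),
    ("Y1", "single", "excitation"),
    ("Y2", "single", "excitation"),
    ("Y2p", "single", "pseudoexcitation"),
    ("O", "single", "output"),
    ("M1", "double", "memory gate"),
    ("M2", "double", "memory gate (learned association)"),
    ("M2p", "double", "pseudomemory gate"),
    ("W1", "double", "waiting"),
    ("W2", "double", "waiting"),
    ("S", "double", "reservoir"),
    ("R1", "double", "reward"),
    ("R2", "double", "reward"),
)


def build_two_input_circuit(params: CircuitParams | None = None) -> ReactionNetwork:
    """The 14-species, 5-reversible + 2-degradation reflex network.

    Reactions (all reversible exchanges at the shared rates):

    - r1: ``I1 + M1 <=> Y1 + W1``   (input 1 excites)
    - r2: ``Y1 + S  <=> O  + R1``   (excitation releases output)
    - r3: ``Y2 + S  <=> O  + R2``   (run backwards, output generates Y2)
    - r4: ``I2 + M2 <=> Y2 + W2``   (run backwards, Y2+W2 charge memory)
    - r5: ``I2 + M2p <=> Y2p + W2`` (input 2 parks on the pseudogate)
    - d1/d2: ``I1 -> waste``, ``I2 -> waste`` (renewal)

    Degradation acts only on the free input strands; inputs bound inside
    waiting duplexes are protected.
    """
    p = params or CircuitParams()
    init = dict(p.init)
    species = [
        SpeciesSpec(name, initial_concentration=init.pop(name, 0.0),
                    strandedness=ss, role=role)
        for name, ss, role in TWO_INPUT_SPECIES
    ]
    if init:
        raise ConfigurationError(
            f"init names unknown species: {sorted(init)}"
        )
    kf, kb = p.k_forward, p.k_backward
    reactions = [
        Reaction(("I1", "M1"), ("Y1", "W1"), kf, kb, label="r1"),
        Reaction(("Y1", "S"), ("O", "R1"), kf, kb, label="r2"),
        Reaction(("Y2", "S"), ("O", "R2"), kf, kb, label="r3"),
        Reaction(("I2", "M2"), ("Y2", "W2"), kf, kb, label="r4"),
        Reaction(("I2", "M2p"), ("Y2p", "W2"), kf, kb, label="r5"),
        Reaction(("I1",), (), p.k_d1, label="d1"),
        Reaction(("I2",), (), p.k_d2, label="d2"),
    ]
    return ReactionNetwork(species, reactions)


VALID_TOKENS = ("F", "B", "FB")
#: Which input strand each token letter doses.
TOKEN_DOSES = {"F": ("I1",), "B": ("I2",), "FB": ("I1", "I2")}


@dataclass(frozen=True)
class InputPattern:
    """An ordered sequence of input presentations.

    ``tokens`` are drawn from {F, B, FB}; consecutive presentations are
    ``interval`` seconds apart (default 5 h) and the simulation runs for
    ``post_window`` seconds after the last one.
    """

    tokens: tuple[str, ...]
    interval: float = DEFAULT_INTERVAL
    post_window: float = DEFAULT_INTERVAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ConfigurationError("pattern must contain at least one token")
        for tok in self.tokens:
            if tok not in VALID_TOKENS:
                raise ConfigurationError(
                    f"unknown input token {tok!r}; expected one of "
                    f"{VALID_TOKENS}"
                )
        if self.interval <= 0 or self.post_window <= 0:
            raise ConfigurationError("interval and post_window must be > 0")

    @property
    def event_times(self) -> list[float]:
        return [i * self.interval for i in range(len(self.tokens))]

    @property
    def horizon(self) -> float:
        return self.event_times[-1] + self.post_window

    def to_schedule(self, dose_amount: float) -> DoseSchedule:
        events = [
            DoseEvent(t, strand, dose_amount)
            for t, tok in zip(self.event_times, self.tokens)
            for strand in TOKEN_DOSES[tok]
            if dose_amount > 0
        ]
        return DoseSchedule(events=events, horizon=self.horizon)


def parse_pattern(
    pattern: str,
    interval: float = DEFAULT_INTERVAL,
    post_window: float = DEFAULT_INTERVAL,
) -> InputPattern:
    """Parse a pattern string such as ``"B-FB-B"`` (en-dash accepted)."""
    normalized = pattern.replace("–", "-").replace("−", "-")
    tokens = [t.strip() for t in normalized.split("-")]
    for tok in tokens:
        if tok not in VALID_TOKENS:
            raise ConfigurationError(
                f"cannot parse token {tok!r} in pattern {pattern!r}; "
                f"expected tokens from {VALID_TOKENS}"
            )
    return InputPattern(tuple(tokens), interval=interval,
                        post_window=post_window)


@dataclass(frozen=True)
class EventMetrics:
    token: str
    dose_time: float
    output_peak: float
    output_end: float


@dataclass
class MetricsReport:
    """Per-presentation output response and memory-gate readings.

    ``memory_levels[k]`` is the M2 concentration at the end of the k-th
    inter-event window (just before the next dose, or at the horizon).
    """

    per_event: list[EventMetrics]
    memory_levels: list[float]
    learning_efficiency: float | None = None

    def to_dict(self) -> dict:
        return {
            "per_event": [
                {"token": e.token, "dose_time_s": e.dose_time,
                 "output_peak_nM": e.output_peak,
                 "output_end_nM": e.output_end}
                for e in self.per_event
            ],
            "memory_levels_nM": list(self.memory_levels),
            "learning_efficiency_pct": self.learning_efficiency,
        }


def run_pattern(
    params: CircuitParams,
    pattern: InputPattern | str,
    solver: SolverConfig | None = None,
) -> tuple[Trajectory, MetricsReport]:
    """Simulate an input pattern and extract per-event response metrics.

    The peak-search window for event k is ``[t_k, t_{k+1})`` (or up to the
    horizon for the last event); the "steady-state" reading is the value
    just before the next dose.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    network = build_two_input_circuit(params)
    traj = simulate(network, pattern.to_schedule(params.dose_amount),
                    solver=solver)
    per_event: list[EventMetrics] = []
    memory: list[float] = []
    times = pattern.event_times
    for k, (tok, t0) in enumerate(zip(pattern.tokens, times)):
        t1 = times[k + 1] if k + 1 < len(times) else pattern.horizon
        om = window_metrics(traj, "O", (t0, t1))
        mm = window_metrics(traj, "M2", (t0, t1))
        per_event.append(EventMetrics(tok, t0, om.peak, om.end_value))
        memory.append(mm.end_value)
    return traj, MetricsReport(per_event=per_event, memory_levels=memory)


def learning_efficiency(post_peak: float, pre_peak: float) -> float:
    """Conditioned-response efficiency in percent.

    The peak of the I2-induced output in the postlearning condition divided
    by the I1-induced output in the prelearning condition, times 100.
    """
    if pre_peak <= 0:
        raise ConfigurationError(
            f"prelearning peak must be > 0 to define an efficiency, "
            f"got {pre_peak}"
        )
    return 100.0 * post_peak / pre_peak


def forgetting_experiment(
    params: CircuitParams,
    n_unpaired: int = 9,
    interval: float = DEFAULT_INTERVAL,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """Normalized output-peak series under one paired then repeated
    unpaired presentations (pattern ``FB-B-B-...``).

    Returns one peak per presentation, each divided by the peak of the
    first (FB) presentation.  The series decays as the unpaired B inputs
    drain the memory gate: the conditioned reflex is gradually forgotten.
    """
    pattern = InputPattern(("FB",) + ("B",) * n_unpaired, interval=interval)
    _, report = run_pattern(params, pattern, solver=solver)
    peaks = np.array([e.output_peak for e in report.per_event])
    if peaks[0] <= 0:
        raise ConfigurationError(
            "first-presentation output peak is zero; cannot normalize "
            "(did the doses vanish?)"
        )
    return peaks / peaks[0]


@dataclass(frozen=True)
class SyncPoint:
    interval: float
    m2_after_second: float
    third_event_peak: float
    m2_normalized: float
    peak_normalized: float


def synchronization_experiment(
    params: CircuitParams,
    intervals: Sequence[float],
    second_gap: float = DEFAULT_INTERVAL,
    solver: SolverConfig | None = None,
) -> list[SyncPoint]:
    """Learning as a function of input-timing synchronization.

    Pattern F-B-B where the F→B gap sweeps over ``intervals`` (seconds)
    and the gap between the second and third presentations is fixed at
    5 h.  For each gap, reads M2 just before the third presentation and
    the output peak it elicits, both normalized by the simultaneous
    (gap 0) case.  Learning requires the I1-induced Y2 to still be present
    when I2's W2 appears, so both quantities fall off with the gap.
    """
    for g in intervals:
        if g < 0:
            raise ConfigurationError("intervals must be >= 0")

    def one(gap: float) -> tuple[float, float]:
        network = build_two_input_circuit(params)
        t2, t3 = gap, gap + second_gap
        events = [DoseEvent(0.0, "I1", params.dose_amount)]
        for t, strand in ((t2, "I2"), (t3, "I2")):
            events.append(DoseEvent(t, strand, params.dose_amount))
        schedule = DoseSchedule(events=events, horizon=t3 + second_gap)
        traj = simulate(network, schedule, solver=solver)
        # M2 read at the end of the window following the second input
        m2 = window_metrics(traj, "M2", (t2, t3)).end_value
        peak = window_metrics(traj, "O", (t3, t3 + second_gap)).peak
        return m2, peak

    m2_ref, peak_ref = one(0.0)
    if m2_ref <= 0 or peak_ref <= 0:
        raise ConfigurationError(
            "simultaneous-input reference response is zero; cannot normalize"
        )
    out = []
    for g in intervals:
        m2, peak = one(g) if g != 0.0 else (m2_ref, peak_ref)
        out.append(SyncPoint(g, m2, peak, m2 / m2_ref, peak / peak_ref))
    return out
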