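"""The n-input generalized conditioned-reflex circuit.

Input I1 is the unconditioned stimulus; I2..In are neutral stimuli, each
carried by its own memory-gate / pseudogate / reward-gate channel wired
to the shared reservoir S and output O.  Training with a simultaneous
combination containing I1 charges the memory gates of every co-presented
neutral channel, after which any of those channels (or I1 itself) elicits
output: the circuit generalizes the conditioned reflex across channels.

``truth_table_experiment`` exhaustively simulates two-presentation input
histories and classifies the second-presentation output peak against a
responsiveness threshold, comparing each call with the combinatorial
expectation (``expected_truth``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from .crn import (
    ConfigurationError,
    DoseEvent,
    DoseSchedule,
    Reaction,
    ReactionNetwork,
    SolverConfig,
    SpeciesSpec,
    simulate,
    window_metrics,
)
from .circuit import CircuitParams, InputPattern, run_pattern

__all__ = [
    "InputCombination",
    "HistoryResult",
    "TruthTable",
    "build_n_input_circuit",
    "expected_truth",
    "enumerate_histories",
    "truth_table_experiment",
    "prelearning_reference_peak",
    "DEFAULT_HISTORY_INTERVAL",
]

#: Interval between the two presentations of a history (s).  10 h: long
#: enough for the circuit to renew fully after the first presentation, so
#: residual excitation strands do not blur the responsiveness calls.
DEFAULT_HISTORY_INTERVAL = 36000.0


@dataclass(frozen=True)
class InputCombination:
    """A set of inputs presented simultaneously, as a bit vector.

    ``bits[k]`` is 1 if input I(k+1) is included.  ``InputCombination.of(
    4, 1, 3)`` builds the 4-channel combination {I1, I3}.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if any(b not in (0, 1) for b in self.bits):
            raise ConfigurationError("combination bits must be 0 or 1")

    @classmethod
    def of(cls, n: int, *channels: int) -> "InputCombination":
        bits = [0] * n
        for c in channels:
            if not 1 <= c <= n:
                raise ConfigurationError(f"channel {c} outside 1..{n}")
            bits[c - 1] = 1
        return cls(tuple(bits))

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def channels(self) -> tuple[int, ...]:
        """1-based indices of the included inputs."""
        return tuple(k + 1 for k, b in enumerate(self.bits) if b)

    def __contains__(self, channel: int) -> bool:
        return 1 <= channel <= self.n and self.bits[channel - 1] == 1

    def label(self) -> str:
        return "+".join(f"I{k}" for k in self.channels) or "(none)"


def build_n_input_circuit(
    n: int, params: CircuitParams | None = None
) -> ReactionNetwork:
    """The generalized reflex network with ``n`` input channels.

    Core species {I1, Y1, M1, W1, S, O, R1} plus, per neutral channel
    k = 2..n, {Ik, Yk, Ykp, Mk, Mkp, Wk, Rk}.  Reactions mirror the
    two-input construction channel by channel:

    - ``I1 + M1 <=> Y1 + W1`` and ``Y1 + S <=> O + R1``
    - per k: ``Ik + Mk <=> Yk + Wk``, ``Ik + Mkp <=> Ykp + Wk``,
      ``Yk + S <=> O + Rk``
    - degradation ``Ik -> waste`` for every input.

    Initial concentrations: M1, every pseudogate Mkp, S and every reward
    gate Rk (k >= 2) at the gate level (default 100 nM); R1 at half of it
    (default 50 nM); all else 0.  The degradation rate of channel 1 is
    ``k_d1``; every neutral channel uses ``k_d2``.
    """
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    p = params or CircuitParams()
    init = dict(p.init)
    gate = init.get("M1", 100.0)
    r1_init = init.get("R1", 50.0)

    species = [
        SpeciesSpec("I1", role="input (unconditioned stimulus)"),
        SpeciesSpec("Y1", role="excitation"),
        SpeciesSpec("M1", gate, "double", "memory gate"),
        SpeciesSpec("W1", 0.0, "double", "waiting"),
        SpeciesSpec("S", init.get("S", gate), "double", "reservoir"),
        SpeciesSpec("O", role="output"),
        SpeciesSpec("R1", r1_init, "double", "reward"),
    ]
    kf, kb = p.k_forward, p.k_backward
    reactions = [
        Reaction(("I1", "M1"), ("Y1", "W1"), kf, kb, label="r1"),
        Reaction(("Y1", "S"), ("O", "R1"), kf, kb, label="r2"),
        Reaction(("I1",), (), p.k_d1, label="d1"),
    ]
    for k in range(2, n + 1):
        mkp = init.get("M2p", gate) if k == 2 else gate
        rk = init.get("R2", gate) if k == 2 else gate
        species += [
            SpeciesSpec(f"I{k}", role="input (neutral stimulus)"),
            SpeciesSpec(f"Y{k}", role="excitation"),
            SpeciesSpec(f"Y{k}p", role="pseudoexcitation"),
            SpeciesSpec(f"M{k}", 0.0, "double", "memory gate"),
            SpeciesSpec(f"M{k}p", mkp, "double", "pseudomemory gate"),
            SpeciesSpec(f"W{k}", 0.0, "double", "waiting"),
            SpeciesSpec(f"R{k}", rk, "double", "reward"),
        ]
        reactions += [
            Reaction((f"I{k}", f"M{k}"), (f"Y{k}", f"W{k}"), kf, kb,
                     label=f"r_mem{k}"),
            Reaction((f"I{k}", f"M{k}p"), (f"Y{k}p", f"W{k}"), kf, kb,
                     label=f"r_pseudo{k}"),
            Reaction((f"Y{k}", "S"), ("O", f"R{k}"), kf, kb,
                     label=f"r_out{k}"),
            Reaction((f"I{k}",), (), p.k_d2, label=f"d{k}"),
        ]
    return ReactionNetwork(species, reactions)


def expected_truth(
    first: InputCombination, second: InputCombination
) -> bool:
    """Whether generalized conditioning predicts a response to ``second``
    after training with ``first``.

    The trained circuit responds to a combination iff it contains the
    unconditioned stimulus I1 or any channel co-presented with I1 during
    training.  ``first`` must contain I1 (the training combination).
    """
    if 1 not in first:
        raise ConfigurationError(
            "training combination must contain the unconditioned stimulus I1"
        )
    if first.n != second.n:
        raise ConfigurationError("combinations must have equal channel count")
    return (1 in second) or any(k in first for k in second.channels if k != 1)


def enumerate_histories(
    n: int, mode: str = "single_second"
) -> list[tuple[InputCombination, InputCombination]]:
    """All two-presentation input histories for the n-channel circuit.

    First presentations are the 2^(n-1) combinations containing I1.
    ``mode="single_second"`` pairs each with the n single-input seconds
    (n=4: 32 histories); ``mode="all_second"`` with every non-empty
    combination (n=4: 8 x 15 = 120 histories).
    """
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    if mode not in ("single_second", "all_second"):
        raise ConfigurationError(f"unknown enumeration mode {mode!r}")
    firsts = [
        InputCombination.of(n, 1, *extra)
        for m in range(n)
        for extra in itertools.combinations(range(2, n + 1), m)
    ]
    if mode == "single_second":
        seconds = [InputCombination.of(n, k) for k in range(1, n + 1)]
    else:
        seconds = [
            InputCombination.of(n, *chans)
            for m in range(1, n + 1)
            for chans in itertools.combinations(range(1, n + 1), m)
        ]
    return [(f, s) for f in firsts for s in seconds]


@dataclass(frozen=True)
class HistoryResult:
    first: InputCombination
    second: InputCombination
    output_peak_second: float
    responsive: bool
    expected_responsive: bool

    @property
    def trivial(self) -> bool:
        """True when the second presentation contains I1 (always responds)."""
        return 1 in self.second


@dataclass
class TruthTable:
    """Exhaustive history classification plus summary counts."""

    results: list[HistoryResult]
    threshold: float

    @property
    def n_responsive(self) -> int:
        return sum(r.responsive for r in self.results)

    @property
    def n_nontrivial_responsive(self) -> int:
        return sum(r.responsive and not r.trivial for r in self.results)

    @property
    def n_expected(self) -> int:
        return sum(r.expected_responsive for r in self.results)

    @property
    def all_agree(self) -> bool:
        return all(r.responsive == r.expected_responsive for r in self.results)

    def to_rows(self) -> list[dict]:
        return [
            {"first": r.first.label(), "second": r.second.label(),
             "peak_nM": r.output_peak_second, "responsive": r.responsive,
             "expected": r.expected_responsive}
            for r in self.results
        ]


def prelearning_reference_peak(
    params: CircuitParams | None = None,
    solver: SolverConfig | None = None,
) -> float:
    """Output peak of a single unconditioned (F) presentation on the
    two-input circuit -- the reference scale for responsiveness calls."""
    p = params or CircuitParams()
    _, report = run_pattern(p, InputPattern(("F",)), solver=solver)
    return report.per_event[0].output_peak


def run_history(
    n: int,
    first: InputCombination,
    second: InputCombination,
    params: CircuitParams | None = None,
    interval: float = DEFAULT_HISTORY_INTERVAL,
    solver: SolverConfig | None = None,
) -> float:
    """Simulate one two-presentation history; return the second-presentation
    output peak (nM)."""
    p = params or CircuitParams()
    network = build_n_input_circuit(n, p)
    events = [
        DoseEvent(0.0, f"I{k}", p.dose_amount) for k in first.channels
    ] + [
        DoseEvent(interval, f"I{k}", p.dose_amount) for k in second.channels
    ]
    schedule = DoseSchedule(events=events, horizon=2 * interval)
    traj = simulate(network, schedule, solver=solver)
    return window_metrics(traj, "O", (interval, 2 * interval)).peak


def truth_table_experiment(
    n: int,
    params: CircuitParams | None = None,
    threshold: float | None = None,
    mode: str = "single_second",
    interval: float = DEFAULT_HISTORY_INTERVAL,
    solver: SolverConfig | None = None,
) -> TruthTable:
    """Simulate every enumerated history and classify responsiveness.

    The default threshold is 5% of the prelearning unconditioned-stimulus
    peak of the two-input circuit (~0.86 nM at default parameters); a
    second-presentation output peak at or above it counts as responsive.
    """
    p = params or CircuitParams()
    if threshold is None:
        threshold = 0.05 * prelearning_reference_peak(p, solver=solver)
    if threshold <= 0:
        raise ConfigurationError("responsiveness threshold must be > 0")
    results = []
    for first, second in enumerate_histories(n, mode):
        peak = run_history(n, first, second, p, interval=interval,
                           solver=solver)
        results.append(
            HistoryResult(
                first=first,
                second=second,
                output_peak_second=peak,
                responsive=peak >= threshold,
                expected_responsive=expected_truth(first, second),
            )
        )
    return TruthTable(results=results, threshold=threshold)
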