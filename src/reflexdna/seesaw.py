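"""Seesaw threshold gate with azobenzene-style photoswitching.

The reflex circuit's raw output O is analog and modest (a few nM for a
conditioned response).  A seesaw gate binarizes and amplifies it into a
new output strand Z:

- T1 (thresholding): ``O + Tt <=> Tp + Tq`` -- the threshold duplex Tt
  absorbs output, suppressing sub-threshold leak quadratically;
- T2 (gating):       ``O + Tg <=> Z + Ti`` -- output releases Z;
- T3 (fueling):      ``Tf + Ti <=> O + Tw`` -- fuel regenerates O, making
  Z release catalytic in O (amplification).

Renewability is provided optically rather than by degradation: toehold
and recognition domains of O, Tt, Tg and Tf carry azobenzene, so under
blue light (BL, trans form) all three reactions run normally, while under
UV (cis form) the modified forward directions slow by orders of magnitude
and the unmodified reverse directions dominate, driving every gate
species back toward its initial concentration.  Irradiation alternates
between BL (read-out) and UV (reset) segments; mode switching is treated
as instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .crn import (
    ConfigurationError,
    Reaction,
    ReactionNetwork,
    SolverConfig,
    SpeciesSpec,
    Trajectory,
    simulate,
)
from .circuit import CircuitParams, InputPattern, build_two_input_circuit

__all__ = [
    "SeesawParams",
    "IrradiationSchedule",
    "GATE_SPECIES",
    "build_threshold_gate",
    "attach_threshold_gate",
    "run_photoswitched",
]

#: Gate species roster: (name, strandedness, role, default initial nM).
GATE_SPECIES: tuple[tuple[str, str, str, float], ...] = (
    ("Tt", "double", "threshold-gate component (threshold)", 100.0),
    ("Tg", "double", "threshold-gate component (gate)", 100.0),
    ("Tf", "single", "threshold-gate component (fuel)", 100.0),
    ("Tp", "single", "threshold-gate component", 0.0),
    ("Tq", "double", "threshold-gate component", 0.0),
    ("Z", "single", "binarized output", 0.0),
    ("Ti", "double", "threshold-gate component", 0.0),
    ("Tw", "double", "threshold-gate component", 0.0),
)


@dataclass(frozen=True)
class SeesawParams:
    """Rates and initial concentrations of the photoswitchable seesaw gate.

    Under BL the thresholding reaction runs 10x faster than the
    amplification reactions and is forward-biased (backward rate
    ``k_threshold_back``, default equal to the amplification rate), which
    is standard seesaw practice: the threshold duplex wins the competition
    for scarce O and holds it, so sub-threshold output barely leaks into
    Z.  The amplification reactions are symmetric (forward = backward),
    matching the reflex circuit's reversible design.  Under UV the
    azobenzene-modified forward directions are multiplied by
    ``uv_forward_factor`` while reverse rates keep their BL values, so the
    net flow re-initializes the gate.
    """

    k_threshold: float = 5.32e-3
    k_threshold_back: float = 5.32e-4
    k_amplify: float = 5.32e-4
    uv_forward_factor: float = 1e-3
    init: Mapping[str, float] = field(
        default_factory=lambda: {"Tt": 100.0, "Tg": 100.0, "Tf": 100.0}
    )

    def __post_init__(self) -> None:
        if min(self.k_threshold, self.k_threshold_back, self.k_amplify) < 0:
            raise ConfigurationError("gate rate constants must be >= 0")
        if not 0 <= self.uv_forward_factor <= 1:
            raise ConfigurationError(
                "uv_forward_factor must lie in [0, 1] (UV slows the "
                "modified forward directions)"
            )
        for name, c in self.init.items():
            if c < 0:
                raise ConfigurationError(
                    f"initial concentration of {name!r} must be >= 0"
                )


def build_threshold_gate(params: SeesawParams | None = None) -> tuple[
    list[SpeciesSpec], list[Reaction]
]:
    """The gate fragment: species (except the shared O) and the three
    mode-switchable reactions T1-T3."""
    p = params or SeesawParams()
    init = dict(p.init)
    species = [
        SpeciesSpec(name, initial_concentration=init.pop(name, default),
                    strandedness=ss, role=role)
        for name, ss, role, default in GATE_SPECIES
    ]
    if init:
        raise ConfigurationError(f"init names unknown gate species: {sorted(init)}")

    def modes(kf: float, kb: float) -> dict[str, tuple[float, float]]:
        return {"BL": (kf, kb), "UV": (kf * p.uv_forward_factor, kb)}

    reactions = [
        Reaction(("O", "Tt"), ("Tp", "Tq"), p.k_threshold,
                 p.k_threshold_back, label="T1",
                 mode_rates=modes(p.k_threshold, p.k_threshold_back)),
        Reaction(("O", "Tg"), ("Z", "Ti"), p.k_amplify, p.k_amplify,
                 label="T2", mode_rates=modes(p.k_amplify, p.k_amplify)),
        Reaction(("Tf", "Ti"), ("O", "Tw"), p.k_amplify, p.k_amplify,
                 label="T3", mode_rates=modes(p.k_amplify, p.k_amplify)),
    ]
    return species, reactions


def attach_threshold_gate(
    circuit: ReactionNetwork, params: SeesawParams | None = None
) -> ReactionNetwork:
    """Couple the gate to a reflex circuit through the shared output O."""
    if "O" not in circuit.species_names:
        raise ConfigurationError(
            "circuit must expose an output species 'O' to attach the gate"
        )
    species, reactions = build_threshold_gate(params)
    clash = {s.name for s in species} & set(circuit.species_names)
    if clash:
        raise ConfigurationError(
            f"gate species already present in circuit: {sorted(clash)}"
        )
    return ReactionNetwork(
        list(circuit.species) + species,
        list(circuit.reactions) + reactions,
    )


@dataclass(frozen=True)
class IrradiationSchedule:
    """Alternating BL/UV light segments.

    Defaults: 1 h of BL (gate active, output binarized) followed by 4 h of
    UV (gate resetting), repeating from t = 0 and tiling the horizon.
    """

    bl_duration: float = 3600.0
    uv_duration: float = 14400.0
    start_mode: str = "BL"

    def __post_init__(self) -> None:
        if self.bl_duration <= 0 or self.uv_duration <= 0:
            raise ConfigurationError("irradiation durations must be > 0")
        if self.start_mode not in ("BL", "UV"):
            raise ConfigurationError("start_mode must be 'BL' or 'UV'")

    def mode_changes(self, horizon: float) -> list[tuple[float, str]]:
        """Sorted (time, mode) switch points covering [0, horizon]."""
        changes: list[tuple[float, str]] = []
        t = 0.0
        mode = self.start_mode
        while t < horizon:
            changes.append((t, mode))
            t += self.bl_duration if mode == "BL" else self.uv_duration
            mode = "UV" if mode == "BL" else "BL"
        return changes

    def segments(self, horizon: float) -> list[tuple[float, float, str]]:
        changes = self.mode_changes(horizon)
        out = []
        for (t0, m), (t1, _) in zip(changes, changes[1:] + [(horizon, "")]):
            out.append((t0, min(t1, horizon), m))
        return out


def run_photoswitched(
    circuit_params: CircuitParams | None = None,
    gate_params: SeesawParams | None = None,
    pattern: InputPattern | str = "B-FB-B",
    irradiation: IrradiationSchedule | None = None,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Simulate the reflex circuit coupled to the photoswitched gate.

    The input pattern drives the reflex circuit as usual while the gate's
    rate constants alternate between the BL and UV sets at each
    irradiation switch.  Returns the full trajectory (circuit and gate
    species, including the binarized output Z).
    """
    from .circuit import parse_pattern

    cp = circuit_params or CircuitParams()
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    irr = irradiation or IrradiationSchedule()
    network = attach_threshold_gate(build_two_input_circuit(cp), gate_params)
    schedule = pattern.to_schedule(cp.dose_amount)
    return simulate(
        network,
        schedule,
        solver=solver,
        mode_changes=irr.mode_changes(schedule.horizon),
    )
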