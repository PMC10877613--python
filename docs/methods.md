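# Methods

## Model

The circuit is modeled as a well-mixed, isothermal chemical reaction
network under deterministic mass-action kinetics. Species are DNA
strands and duplexes at nM concentrations; reactions are of two kinds:

- **reversible bimolecular exchanges** `A + B <=> C + D` (toehold-mediated
  strand displacement), flux `k_f [A][B] − k_b [C][D]` in nM/s;
- **irreversible unimolecular decays** `A -> waste` (exonuclease-style
  input degradation), flux `k_d [A]`. Waste is implicit: degradation
  products are not tracked, and degradation acts only on the *free* input
  strands — inputs bound inside waiting duplexes are protected, since
  duplexes are treated as stable species.

Units are fixed globally: concentration nM, time s, bimolecular rates
1/(nM·s), unimolecular rates 1/s.

Input administration is an instantaneous concentration increment: at each
event time the dosed amount is added to the state and integration
restarts. This is the cleanest multi-event equivalent of specifying
inputs as initial concentrations per presentation, and it makes dose
composition exact (dosing a+b equals dosing a then b at the same instant,
which is tested as a property).

Sequence-level detail is out of scope: no nucleotide design, no
thermodynamic rate prediction, no spatial or stochastic effects. Rates
enter only as configuration parameters.

## Numerical choices

- Integrator: LSODA (stiff-capable) via `scipy.integrate.solve_ivp`,
  relative tolerance 1e-8, absolute tolerance 1e-10 nM.
- Output grid: at least one sample per 10 s, dense enough that peak
  extraction is grid-independent (halving tolerances and grid moves peaks
  by <0.1%, tested).
- Integration is piecewise between breakpoints (dose times, irradiation
  switches); the sample at a dose time is the post-dose state.
- Solver output may undershoot zero within tolerance; reported
  concentrations are clipped at 0 nM.
- Conservation laws are computed exactly (integer arithmetic via sympy):
  the left null space of the full stoichiometric matrix gives the
  degradation-proof groups, completed to the null space of the
  reversible-only matrix to identify groups broken by degradation. The
  two-input circuit has 7 intact and 2 broken groups.

## Experiment conventions

- **Event windows.** The response window of presentation k is
  [t_k, t_{k+1}); its "steady-state" reading is the last sample before
  the next dose (or the horizon). Peaks are window maxima.
- **Spacing.** Two-input pattern experiments use a 5 h inter-event
  interval and a 5 h post-window. The original pattern experiments do not
  state their spacing; 5 h is the interval fixed by the synchronization
  protocol and is applied uniformly, exposed as configuration.
- **Doses.** 100 nM per input per presentation; an FB presentation doses
  both inputs at the same instant.
- **Learning efficiency** is the postlearning I2-induced peak divided by
  the prelearning I1-induced peak, ×100.

## Renewability

Renewal is asymptotic, driven by input degradation pulling the reversible
cascade backward. 5 h after a lone F presentation the M1/W1
redistribution still deviates ~2.7 nM from initial and decays with a
multi-hour tail; renewability is therefore asserted 10 h after a
presentation, where every species is within 2 nM (2% of the 100 nM input
scale). After a *learning* presentation the memory cannot renew alone:
the conservation laws {Y2+R2+M2}, {S+R1+R2}, {M1+W1} force R2, R1, M1,
W1 and Y2p to shift alongside the ~16.5 nM stored in M2. The free
strands and the reservoir do return to initial, which is what the
renewability tests assert.

## Generalized circuit

The n-input construction replicates the neutral channel (memory gate,
pseudogate, waiting, reward, excitation species) per input k ≥ 2, all
sharing the reservoir S and output O. A two-presentation history
(first, second) is classified **responsive** if the second-presentation
output peak reaches a threshold, by default 5% of the prelearning
unconditioned-stimulus peak (~0.86 nM).

The two presentations are spaced **10 h** apart (the two-input pattern
experiments use 5 h). The separation matters: the O → R_k feedback that
implements learning also leaves ~1 nM of residual excitation strand Y_k
on *untrained* channels 5 h after a bare-I1 presentation, which blurs the
responsive/non-responsive margin. At 10 h the circuit has fully renewed:
untrained single-input responses stay below 0.55 nM while trained ones
exceed 1.37 nM, so the classification is robust to any threshold in
roughly 3–8% of the prelearning peak, and the 4-input truth tables (12
non-trivial responsive of 32; all 120 histories matching the
combinatorial expectation) are exact.

## Seesaw threshold gate

The gate couples to the circuit through the shared output O with three
reversible reactions: thresholding `O + Tt <=> Tp + Tq`, gating
`O + Tg <=> Z + Ti`, and fueling `Tf + Ti <=> O + Tw`; the last two form
a catalytic cycle that releases many Z per O. Defaults under blue light:
thresholding forward 5.32e-3 1/(nM·s) (10× the amplification rate, so the
threshold wins the competition for scarce O) with backward 5.32e-4
(forward-biased, as seesaw thresholds are); amplification symmetric at
5.32e-4. With [Tt]₀ = [Tg]₀ = [Tf]₀ = 100 nM, a 1 nM O pulse leaks
<0.3 nM of Z in a 1 h read window while a 50 nM pulse releases >50 nM —
the sigmoid-like binarization.

Photoswitching is modeled as mode-dependent rate constants only: under UV
the azobenzene-modified forward directions are multiplied by 1e-3 while
reverse rates keep their blue-light values, so all three reactions run
net-backward and the gate re-initializes. Which directions are
azobenzene-suppressed is a documented assumption (the forward, O-consuming
directions); trans/cis photoconversion kinetics are not modeled, and mode
switches are instantaneous. Irradiation alternates 1 h BL / 4 h UV by
default. On the learning pattern B-FB-B this yields binarized peaks of
~0 / ~50 / ~16 nM — the conditioned response amplified well above its raw
3.8 nM — with the gate returning to within 2 nM of initial after each UV
segment.

## Parameter estimation

The design cost is built from four response statistics: peak and
steady-state output of (a) a simultaneous I1+I2 presentation at
prelearning and (b) an I2 presentation at postlearning (one training
presentation, then one 5 h interval). The default form is

    J = −J_pk⁽²⁾ + α (J_ss⁽¹,²⁾ + J_ss⁽²⁾),  α = 1,

maximizing the conditioned response while penalizing failure to renew;
the weights and functional form are a strategy object so alternatives can
be swapped without touching the optimizer.

The optimizer is a small seeded genetic algorithm (tournament selection,
BLX-0.5 crossover and gaussian mutation on real genes, uniform crossover
and random-reset mutation on integer genes, elitism). Decision variables:
the five nonzero initial concentrations (0–200 nM), the two degradation
rates (log-uniform 1e-4–1), and four integer toehold lengths in 3–6 nt
indexing a length → rate lookup table. Only the 5-nt entry of that table
(5.32e-4 1/(nM·s)) is an anchored measurement; the 3/4/6-nt entries are
order-of-magnitude placeholders (strand-displacement rates climb roughly
tenfold per toehold nucleotide before saturating) that shape GA
exploration only. Which toehold domain governs which reaction is likewise
a structural assumption (`TOEHOLD_ASSIGNMENT`). Seeded runs are
bit-reproducible; reported estimates follow the one-significant-digit
convention (`round_to_one_significant`).

A generic local-sensitivity utility (central finite differences of any
response statistic, normalized as d log metric / d log parameter) stands
in for a full sensitivity study.

## Problem sizes

All computations are desk-scale: a three-presentation pattern integrates
14 ODEs over 15 h of simulated time in well under a second; the full
120-history truth table of the 4-input circuit (35 species each) takes
tens of seconds; the test-suite GA runs use small populations (4–40) and
few generations, sufficient for reproducibility and toy-optimum checks.

## Known limitations

- Concentration-level model only: any hidden intermediates or waste
  species of the real strand-displacement pathway are invisible here.
- The azobenzene gate's UV rate set is a single multiplicative factor;
  real photoswitching is gradual and wavelength/placement dependent.
- The toehold → rate table and toehold → reaction assignment are
  configuration, not predictions; estimation results depend on them.
- The 2% renewability figure is tied to the 100 nM dose scale; much
  larger doses renew more slowly.
- Learning efficiency dilutes as input channels are added (tested down to
  monotonicity, not to a quantitative law); the 10-input case is exercised
  only as a construction smoke test.
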