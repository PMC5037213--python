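# Methods

## Model overview

`lipidsim` simulates the de novo lipid metabolism of a budding yeast cell over
one 120-minute cell cycle.  It is a hybrid of rule-based/agent-based modeling
and tau-leaping: lipids are attribute-carrying objects (class, head group,
acyl chains, localization) and reactions are promiscuous rules that transform
whole substrate classes, while time advances in fixed 1-second steps in which
every rule may fire multiple times.

Two parameters govern each rule. `n_max` is the maximum number of executions
per step, the stochastic counterpart of a Vmax.  The probability that one
execution takes place is a product of Michaelis–Menten saturation terms, one
per substrate,

    p = prod_S  [S] / (Km_S + [S]),

evaluated once per step from the state at the step's start.  The per-step
execution count is therefore Binomial(n_max, p).  The implementation draws
that binomial directly; the literal protocol — draw n_max uniforms, execute
once per uniform below p — is kept as `draw_executions_loop` and the test
suite verifies the two agree in mean and variance over 1e5 trials.  With this
construction, a single isolated rule at constant substrate reproduces the
deterministic Michaelis–Menten flux n_max·[S]/(Km+[S]) on average, which the
suite also checks (within three standard errors over 1e4 steps).

Within a step the protocol is: (1) compute all rule probabilities from the
start-of-step state; (2) randomly permute the rule order; (3) execute each
rule its drawn number of times; (4) replenish precursor pools by their
constant refill rates; (5) run the transport stage.  Executions that find
their substrates already consumed earlier in the same step are silent no-ops
(tau-leap-style post-hoc clipping), so no pool or tally can go negative.

All counts are *model units* of 10^4 real molecules, including Km values.
The random number generator is numpy's PCG64; one seed fixes a trajectory
bit-for-bit.

## Exchangeable-object state representation

Lipids of identical (class, chain composition) are statistically
exchangeable, so the state stores integer count vectors over each class's
enumerated chain-composition space rather than retained Python objects
(`Lipid` objects are materialized at the API surface, where their structural
invariants — chain count per class, sn2 unsaturation, head-group/class
correspondence, C26:0 confined to sphingolipids — are enforced).  Selecting k
random substrate objects is then one multivariate-hypergeometric draw, which
is distribution-identical to removing k uniformly random objects one at a
time, and a batch of k executions is applied at once.  This keeps a full
7200-step run to a few seconds on one CPU without changing the statistics of
the per-object execution protocol.

## Network

Twenty lumped rules connect central-carbon precursors (pyruvate, DHAP,
glycerol 3-phosphate, CTP, serine, glucose 6-phosphate, ceramide) to the
membrane lipidome: acyl-chain synthesis (8 acetyl-CoA per C16 chain, 9 per
C18, 13 for the sphingolipid C26:0; desaturation folded into the categorical
species draw), backbone acylation to lysoPA and PA (sn1 takes any chain, sn2
only unsaturated ones), CTP activation to CDP-DG, head-group chemistry to
PI / PS / PE / PC and cardiolipin (one CL object carries the four chains of
its two CDP-DG donors), the PA–DAG–TAG storage branch, a lumped ergosterol
synthesis (18 acetyl-CoA per sterol) with steryl-ester formation, and a
lumped sphingolipid synthesis.  The TAG lipase and SE hydrolase that mobilize
the storage lipids are phase-gated to S/G2/M, mirroring their
cell-cycle-dependent activation.  The Kennedy scavenging pathway,
inter-membrane transport, degradation beyond the two storage hydrolases, and
energy/redox coupling are deliberately out of scope.

Design choice: the sphingolipid rule transfers the inositol-phosphate head
group of a PI onto a ceramide and *releases the PI's diacylglycerol* into the
free DAG pool (as the real MIPC synthesis does).  Without that byproduct the
consumed PI's chains would vanish, breaking the exact chain and carbon
bookkeeping the tests rely on.

Carbon conservation is tracked exactly: cumulative acetyl-CoA consumption
always equals 8·(#C16 chains) + 9·(#C18) + 13·(#C26) + 18·(#ergosterol)
synthesized.

## Transport, membranes, droplet

Nine compartments are modeled: plasma membrane, secretory vesicles, vacuole,
nucleus, peroxisome, light microsomes, inner and outer mitochondrial
membranes, and the lipid droplet.  Each step, 10% of every free membrane
lipid class (stochastically rounded, so small pools are not systematically
stranded) is distributed among the eight bilayer membranes with probabilities
proportional to size_weight × composition_target, renormalized per class; a
class never enters a membrane whose target fraction for it is zero
(cardiolipin stays mitochondrial).  Membranes are absorbing sinks.  The
default size weights equal each membrane's expected net growth over the
cycle, so that a production mix matching aggregate demand reproduces the
final membrane sizes; intermediates (lysoPA, CDP-DG) have no targets and are
never transported.  Each transported object draws its destination membrane
independently (stochastic apportionment rather than deterministic splitting).

The droplet exchanges TAG and steryl esters with the free pools through
constant phase-dependent fluxes: influx of an (availability-limited) 50:50
TAG/SE mix during G1, efflux afterwards until empty.  It is the only
compartment allowed to shrink and shows the largest relative ensemble spread.

## Initialization

Membrane sizes start from measured or estimated areas converted with
5×10^6 lipids per µm² of bilayer and the 10^4 scale (e.g. the 50 fL spherical
cell gives 65.9 µm² → 32950 units of plasma membrane; the nucleus 12 µm² →
6000 units).  Each run multiplies every membrane size by (1 + ε), ε uniform
in ±5%, then draws class tallies multinomially from the composition targets.
Initial chain compositions follow the configured fatty-acid distribution with
the sn2 constraint honoured: sn2 positions carry the unsaturated species with
renormalized weights and sn1 positions compensate, so the seeded chain pool
matches the target marginal.  Free pools start at 5% of each membrane
resident class (plus small lysoPA/CDP-DG pipeline pools and 60 free chains);
the droplet starts at 1000 units of 50:50 TAG/SE (10^7 lipids).

## Parameterization and calibration

The model's quantitative anchors are: final membrane sizes (plasma
32950 → 60195 units with ~96,000 total; Table of benchmark finals in
`tests/test_acceptance.py`), the esterified fatty-acid distribution
(50% C18:1, 30% C16:1, 9% C16:0, 11% lumped C18:0), the plasma-membrane
ergosterol-to-phospholipid ratio 0.94, and the two perturbation responses
(~30% ergosterol-content reduction and ~80,000 total lipids under sterol
knockout; ~+5 percentage points of vacuolar PI under inositol feeding with
unchanged growth).  Two reaction maxima are fixed a priori:
n_max(acetyl-CoA synthase) = 650 and n_max(PC synthase) = 5.

All remaining defaults (refill rates, Km values, the remaining n_max values,
composition-target matrix, droplet flux magnitudes) are the package's own
calibrated parameterization.  The calibration logic: composition targets and
membrane growth imply a per-class demand T_c = Σ_m growth_m × target_{m,c};
refill rates of the flux-forcing precursors (pyruvate, triose phosphates,
CTP, serine, glucose 6-phosphate, ceramide) are set to the implied pathway
fluxes; n_max values are sized ~2× the required flux so pools self-stabilize
at roughly their Km (if a pool falls, its consumers slow below the refill and
it recovers); Km values of fast-turnover intermediates (PA, DAG) are small so
consumption outcompetes the 10%/step transport skim.  Residual mismatches
were resolved by iterated simulation against the anchors above (manual
stepwise refinement, smaller corrections as the fit improves).  The defaults are
frozen in `lipidsim.config` and exportable as YAML.

The ergosterol-knockout summary averages the per-membrane relative reduction
of the ES fraction *weighted by each membrane's ergosterol content* (i.e. the
reduction of the cell's membrane sterol pool).  An unweighted average is
structurally forced to ~40% or more under these growth targets, because
membranes that triple or quadruple (vacuole, nucleus) dilute their sterol
almost completely once synthesis stops; the content-weighted mean is the
summary that a whole-cell sterol measurement would report.  The droplet is
excluded (it stores esters, not free sterol).

The inositol experiment's default supplementation flux equals the baseline
glucose-6-phosphate refill (the de novo inositol capacity).  Because the PI
synthase probability saturates in both inositol and CDP-DG, the response is
capped by design: PI production rises ~20% irrespective of how much inositol
accumulates, reproducing the qualitative (not the experimentally reported
massive) PI increase, largest in the PI-rich vacuolar membrane.

## Numerical and edge-case conventions

- Precursor pools are floats (refills may be fractional and are applied
  exactly); consumption is integer and clipped to availability.
- Stochastic rounding (floor + Bernoulli on the fraction) is used wherever a
  fractional per-step quantity must become a count (10% transport, droplet
  fluxes).
- Composition fractions of an empty membrane raise an error rather than
  returning NaN.
- `horizon = 0` is a valid configuration producing a length-1 trajectory.
- Ensemble member i uses `SeedSequence(entropy=base_seed, spawn_key=(i,))`,
  so any single run is re-derivable from the master seed and its index.

## Problem sizes used by the shipped checks

Benchmark comparisons use 20-run ensembles of the full 7200-step cycle per
condition (control, sterol knockout, inositol supplementation); the benchmark
means were originally estimated from 1000-run ensembles, but they are stable
to well within the comparison tolerances at 20 runs (the plasma-membrane ensemble sd
is ~1.5% of its mean).  The randomized-invariant fuzz covers twelve perturbed
parameterizations × 800 steps; the binomial-vs-loop equivalence uses 1e5
trials.  Trajectories are sampled every 10 s by default (721 records per
run); set `sample_interval` to 1 s for per-step records.

## Known limitations

- Measured per-reaction kinetic constants are not available for these lumped
  steps; the shipped defaults are calibrated to the benchmark anchors, and
  per-reaction values (other than the two anchored maxima) should be read as
  plausible, not measured.
- Membrane compositions are steered by the transport targets rather than
  emergent; the model cannot predict compositions it was not pointed at.
- Within a step, a rule's probability is not re-evaluated after upstream
  rules consume substrates (fixed-step tau-leap error); newly produced
  lipids can be skimmed by transport one step before their consumers see
  them, which slightly enriches membranes in short-lived intermediates
  such as PA.
- No leaflet asymmetry, lipid geometry, inter-membrane exchange, droplet
  monolayer, or energetic coupling.
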