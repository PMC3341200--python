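# Methods

## Model

The model is a deterministic mass-action ODE system over 15 state
variables (amounts in an arbitrary unit, au; time in minutes): free MITF
in four phosphorylation states (unphosphorylated, S73, S409, S73+S409),
free PIAS3, the four MITF–PIAS3 complexes, RSK1 and phospho-RSK1
(conserved total, 500 au by default), STAT3, phospho-STAT3, the
PIAS3–STAT3p complex, and the dimensionless ubiquitinated fraction *R*
of S73-phosphorylated MITF. Phospho-ERK and phospho-JAK are
piecewise-constant inputs, 10 au each at rest.

Reactions:

- ERK phosphorylates MITF at S73 (rate constant `k_Mp73E_plus`, applied
  to free and PIAS3-bound MITF alike); MITF also autophosphorylates at
  S73 (`k_Mp73a_plus`); one shared dephosphorylation rate
  (`k_Mp73_minus`).
- ERK phosphorylates RSK1 (`k_Rp_plus`/`k_Rp_minus`); phospho-RSK1
  phosphorylates MITF at S409 (`k_Mp409_plus`/`k_Mp409_minus`).
- Each MITF phospho-form binds PIAS3 with its own association and
  dissociation constants; S73 phosphorylation raises the affinity,
  S409 phosphorylation nearly abolishes it.
- JAK phosphorylates STAT3 (`k_Sp_plus`/`k_Sp_minus`); phospho-STAT3
  binds PIAS3 (`k_Spass`/`k_Spdiss`).
- MITF, PIAS3 and STAT3 are produced at constant rates and degrade
  linearly; a complex degrades at 20% of the mean of its constituents'
  free-protein rates, `(γ_a + γ_b)/10`.
- S73-phosphorylated MITF (free or bound, singly or doubly
  phosphorylated) contributes its S73 degradation rate `γ_MITFp73` only
  in proportion to *R*; where the doubly phosphorylated form is
  concerned the S409 rate `γ_MITFp409` applies additionally and in
  full. In complex degradation the factor *R* multiplies `γ_MITFp73`
  inside the 20%-of-mean expression.

### Ubiquitination bookkeeping

Rather than doubling the MITF state space once more, ubiquitination is
tracked as the shared ratio *R* of S73-phosphorylated MITF that carries
the tag. Its dynamics sum three processes:

1. tagging of untagged protein: `(1 − R)·ERKp·k_u`;
2. depletion of the tagged pool by its own degradation, derived from the
   ratio after one minute of tagged-pool decay. We use the algebraically
   equivalent singularity-free form
   `−γ·a·R·(1 − R)/(1 − R·γ·a)` with `a = 1 min`, which is regular at
   R = 0 (the printed ratio form divides by R); the equivalence is a
   test, not an assumption;
3. dilution by production of fresh untagged protein:
   `−R·(1 − A)` with `A = B/(B + max(p_MITF − [MITFp409]·γ_MITFp409, 0)·a)`
   and `B = [MITFp73] + [MITFpp]`.

The production influx inside *A* is clamped at zero. Without the clamp,
a large S409 pool (reachable in the strong-transfection protocols)
makes the printed denominator smaller than *B*, pushing A above 1 and
*R* out of [0, 1]; physically, a negative influx of fresh protein into
the S73 pool cannot *concentrate* the tag. With the clamp, A ∈ [0, 1]
always and R stays in [0, 1] along every trajectory, which the test
suite asserts across all 28 protocols.

### Parameters

The 30 core constants ship as the `methods` dialect of
`make_default_parameters`. Two printed values of the PIAS3 production
rate exist (0.262 vs 1.262 au/min); the experiment protocols are all
anchored to 1.262 ("elevated from 1.262 to …"), so `methods` uses 1.262
and maximizes internal consistency of the harness, while `table1`
selects 0.262. The STAT3 production rate is 0.211 au/min in both. One
printed symbol inconsistency (a complex-degradation γ for phospho-STAT3
that appears nowhere in the constant table) is resolved to the STAT3
degradation rate, and one sign/symbol typo in the S409-pool balance is
read as the autophosphorylation loss term required for consistency with
the reaction scheme.

### Activity readouts

MITF transcriptional activity is the linear map
`f = 10 − 0.11·[MITF] + 0.44·[MITFp73] + 0.11·[MITFp409] + 0.56·[MITFpp]`
over free species only; STAT3 activity is free `[STAT3p]`. Ratios
between conditions are taken on raw `f` (offset included), mirroring how
reporter assays are normalized to a control condition. `f` can go
negative under extreme parameter draws; it is returned as computed and a
warning is logged, since ratio criteria lose meaning there.

## The experiment harness

Each protocol is data: conditions (e.g. ±PIAS3 transfection, wild type
vs mutant), each a list of (duration, perturbation) phases; readouts
(named scalars at stated times); and a success criterion (a conjunction
of interval/ratio/ordering clauses with the published bounds).
Transfections are absolute production-rate overrides held for a
2880-minute incubation; mutations override rate constants (S409A zeroes
S409 phosphorylation; S73D zeroes S73 dephosphorylation and raises
autophosphorylation to 5/min; S409D re-parameterizes the RSK1/S409
cycle; STAT3-C makes STAT3 phosphorylation constitutive; Y705F zeroes
it); stimulation replaces the input levels.

Protocol start: the resting steady state at baseline inputs with default
productions — except where a protocol explicitly zeroes MITF pools (the
fibroblast-host experiments) or sets MITF/PIAS3 pools to 1 au. Genotypic
perturbations (the binding-dead MITF of experiment 26) also apply while
computing the resting state, since the mutant cells never had the
wild-type constants.

Interpretation choices the printed protocols leave open (all encoded in
`experiment_catalog`, exported to YAML by `export-catalog`):

- "Activation level elevated from 10 to 20" in the RSK1/PIAS3-activity
  series means phospho-ERK = 20 with phospho-JAK at rest; those
  protocols probe only the MAPK arm.
- The PIAS3-dose experiment treats its four transfection levels
  {0.5, 1, 2, 4} au/min as absolute production rates; its criterion
  (monotone decrease, two-fold span) does not reference a baseline.
- The STAT3-mutant activity experiment's sixth condition is printed
  identically to its fifth; it is read as the constitutively active
  variant, completing the experiment's 2 × 3 transfection design.
- The MITF-transfection/STAT3-activity experiment's untransfected arm
  has zero MITF production: its host fibroblasts express no MITF, the
  same convention the catalog applies to untransfected genes elsewhere
  in that cell line.
- "At least 25% higher" clauses additionally require a strict increase,
  which matters only when both compared amounts degenerate to zero
  (e.g. binding-dead parameter draws).
- "4 hours" readouts are taken 240 minutes after activation;
  "without stimulation" readouts at the resting state.
- RSK1 transfection tops the conserved pool up to 5000 au at phase
  start, arriving unphosphorylated.

Two knife-edge facts worth knowing: the complex-kinetics protocols
(experiments 6 and 7) pass their "complex up at 10 min" clause by less
than 1% at default parameters, so their verdicts are the first to flip
under parameter perturbation; and the MITF-only protocols are coupled
to the STAT3 arm only through the shared free-PIAS3 pool — a weak but
nonzero link.

## Sensitivity analysis

`run_sensitivity` samples each core parameter independently,
log-uniformly on [0.5, 2]× its default (the conserved RSK1 total is not
sampled; experiment-specific overrides are never resampled), runs the
battery per draw, and computes
`s_ij = Σ_{k=1..100} |f_ij^k − f_i|`, where `f_ij^k` is the success rate
of experiment *i* in the *k*-th rank-bin of parameter *j* and `f_i` the
overall rate. Entries not exceeding the maximum statistic under random
permutations of the parameter values are zeroed; rows are normalized by
their maximum for display.

Because the statistic depends on a parameter column only through rank
order, permuting parameter values is equivalent to randomly re-binning
the outcomes — so one shared permutation stream serves all parameter
columns and the null threshold is per-experiment. Ties in sorting break
by sample index (stable sort); under continuous sampling they have
probability zero.

Problem sizes: the published analysis used 10⁶ samples and 10⁴
permutations. This package's defaults are 10⁴ samples and 10³
permutations (`analysis/04_sensitivity.py`, ~20–40 min on one CPU); the
test suite runs a 2 × 10³-sample smoke scan. Per-bin success rates carry
Monte-Carlo noise ~√(n_bins/n), so the permutation threshold rises as n
falls and *weakly* influential parameters drop below it: the scans at
these scales recover the structurally insensitive parameters (the
S409-complex association pair and the MITF production rate, whose
zero-column status is robust) but classify additional weak effects —
most persistently the STAT3 production rate — as null, because their
signal cannot clear a threshold built from 10–100× fewer samples than
the published analysis used. The shipped full-scale driver output
(`results/sensitivity/summary.json` and the matrices beside it) records
this directly. Reported per scan: raw, filtered and normalized
matrices, thresholds, and the set of parameters with zero filtered
sensitivity everywhere.

## Numerics

- Integration: LSODA (scipy's `odeint`) over a numba-compiled RHS,
  restarted at every input breakpoint so steps are exact; rtol 1e-6,
  atol 1e-8 au by default, configurable via `SolverSettings`/`RunConfig`.
- States are never clipped inside the RHS; reporting views floor tiny
  negative excursions at zero. Admissibility (amounts ≥ 0, R ∈ [0, 1])
  is asserted across all protocols in the tests.
- Steady states: integrate 50,000 min (extending to 400,000) and require
  max_i |dx_i/dt| / (|x_i| + 1) < 1e-6; the slowest system mode (the
  unphosphorylated-MITF turnover, ~800 min) is fully relaxed well within
  the horizon. Root-polishing was unnecessary at this tolerance.
- Experiment runs evaluate trajectories only at criterion-relevant
  times (criteria are invariant to the reporting grid); the
  rise-time readout integrates on a 0.1-minute grid.
- Identical inputs give bitwise-identical trajectories; all sampling is
  `numpy.random.Generator`-seeded, and the permutation stream derives
  from the sampling seed.

## The crosstalk asymmetry

Activating the MAPK arm perturbs STAT3 activity more than activating
the JAK arm perturbs MITF activity. This is a *response* property: it
is quantified as the maximal relative excursion of the other factor's
activity during a six-hour activation window (the catalog's longest
activation), where the MAPK step moves STAT3 activity by ~21% against
~14% for the converse. At the infinite-horizon steady state the
contrast inverts, because the slow degradation pools re-equilibrate and
absorb the STAT3 response — a reminder that the network's co-regulation
effects live on specific time scales.

## What the harness does and does not show

The catalog is also the package's fixture generator: every test input is
built from printed protocol numbers, so passing tests show that the
model, as parameterized, reproduces the *formalized* criteria — interval
and ratio bounds on simulated readouts. They do not show fit to raw
band intensities or absolute reporter counts (the sources publish only
relative quantities), and experiment 26 is expected to fail: the
simulated STAT3 response to stimulation is independent of the MITF
genotype, contradicting the lab observation and the sequestration-only
explanation proposed for it.

## Known limitations

- One shared ubiquitination ratio for free and complexed S73-MITF; no
  per-pool tag state.
- Production is a constant rate, not transcription + translation;
  enzymatic steps are mass action, not Michaelis–Menten; activity maps
  are first-order polynomials. Absolute quantitative data would be
  needed before refining any of these.
- The kinase inputs are levels, not pathways: feedbacks upstream of ERK
  and JAK (e.g. SOCS) are out of scope.
- At smoke scale the sensitivity scan's null threshold is high; weak
  effects are only resolved at the full sample size.
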