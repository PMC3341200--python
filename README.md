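# pias3net

An executable model of the **MITF–PIAS3–STAT3** signalling network in
melanocytes: a mass-action ODE system, a catalog of 28 formalized
wet-lab experiments with quantitative pass/fail criteria, and a global
sensitivity analysis of those verdicts over the model's 30 core
parameters.

## The science

The transcription factors **MITF** (the melanocyte master regulator,
activated through the MAPK pathway) and **STAT3** (activated through
JAK) do not touch each other directly — they compete for a common
inhibitor, **PIAS3**. The competition is asymmetric: PIAS3 binds
*activated* (tyrosine-phosphorylated) STAT3 but preferentially
*non-activated* MITF, so activating one factor reshapes the free-PIAS3
pool that gates the other.

The model tracks 15 dynamical quantities: free MITF in its four
phosphorylation states (none, S73, S409, S73+S409), free PIAS3, the four
MITF–PIAS3 complexes, the RSK1/RSK1p kinase pair (conserved total),
STAT3, phospho-STAT3, the PIAS3–STAT3p complex, and a dimensionless
ratio *R* — the ubiquitinated fraction of S73-phosphorylated MITF, which
controls its proteasomal degradation. Phospho-ERK and phospho-JAK enter
as piecewise-constant inputs; "activation" means stepping them (e.g.
10 → 1000 au). Kinetics are simple mass action; complexes degrade at 20%
of the mean of their constituents' rates, i.e. (γ_a + γ_b)/10.

Model states are mapped to what experiments actually measure through two
activity readouts:

    f = A0 + A_M·[MITF] + A_M73·[MITFp73] + A_M409·[MITFp409] + A_Mpp·[MITFpp]

with (A0, A_M, A_M73, A_M409, A_Mpp) = (10, −0.11, 0.44, 0.11, 0.56)
over *free* MITF only (the luciferase-reporter analogue), and free
[STAT3p] for STAT3.

Each of the 28 catalog experiments encodes one published protocol —
transfections as production-rate overrides, mutations as rate-constant
overrides, stimulation as input steps — plus the printed success
criterion (interval, ratio and ordering clauses on the readouts). The
sensitivity module samples the 30 core parameters log-uniformly within
[0.5, 2]× their defaults, re-runs the battery, and scores each
(experiment *i*, parameter *j*) pair by the binned success-rate
statistic s_ij = Σ_k |f_ij^k − f_i| over 100 rank-bins, zeroing entries
that do not beat the maximum observed under random permutations.

## Worked example

```python
from pias3net import make_default_parameters, run_all

params = make_default_parameters("methods")   # published defaults
results = run_all(params)
print(sum(r.passed for r in results.values()), "of", len(results), "pass")
print("failed:", [i for i, r in results.items() if not r.passed])
for clause in results[26].clauses:
    print(" ", "ok" if clause["passed"] else "XX", clause["label"])
```

prints

```
27 of 28 pass
failed: [26]
  ok WT MITF activity doubled at 30 min
  ok WT STAT3 activity doubled at 4 h
  ok mutant MITF activity not doubled at 30 min
  ok mutant MITF activity not doubled at 4 h
  XX mutant STAT3 activity not doubled at 30 min
  XX mutant STAT3 activity not doubled at 4 h
```

i.e. the model accounts for 27 of the 28 published experiments. The sole
failure, #26, compares wild-type MITF against a mutant that cannot bind
PIAS3: in the lab the mutation abolished the STAT3 activation response,
but in the model phospho-STAT3 rises on stimulation regardless of the
MITF genotype — the model cannot reproduce that observation, which
suggests the proposed sequestration mechanism alone does not explain it.

The numbered drivers under `analysis/` walk through the full study:

| driver | what it does |
|---|---|
| `01_baseline_dynamics.py` | resting steady state, activation transients |
| `02_run_experiments.py`   | the 28-experiment battery and clause report |
| `03_crosstalk.py`         | the one-way-crosstalk asymmetry |
| `04_sensitivity.py`       | the global sensitivity scan (default n = 10⁴, ~20–40 min) |

A `pias3net` command-line tool wraps the same operations
(`simulate`, `run-experiment`, `run-all`, `sensitivity`,
`export-catalog`); see `pias3net --help`.

## Notes

- Two published values of the PIAS3 production rate circulate (0.262 vs
  1.262 au/min). The default `methods` dialect uses 1.262, which all
  experiment protocols are anchored to; `table1` selects 0.262.
- `docs/methods.md` documents the model equations, the ubiquitination
  bookkeeping, every protocol-interpretation choice, and the numerical
  settings.
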