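"""Global sensitivity of virtual-experiment success to core parameters.

The analysis asks, for each of the 28 virtual experiments, which of the
30 core parameters its pass/fail outcome is sensitive to:

1. sample ``n`` core-parameter sets, each parameter independently
   log-uniform between 0.5x and 2x its default;
2. run the full experiment battery for each set, giving an ``n x 28``
   boolean outcome matrix with per-experiment overall success rates
   ``f_i``;
3. for each (experiment i, parameter j): sort the samples by parameter
   j, split them into equal rank-bins (100 by default), and sum the
   absolute deviations of the per-bin success rates from ``f_i`` --
   the binned success-rate statistic ``s_ij``;
4. null-filter: zero every ``s_ij`` that does not exceed the maximum
   statistic observed under random permutations of the parameter values
   (which destroy any parameter-outcome association);
5. normalize each experiment's row by its largest surviving entry for
   display.

Because the statistic depends on the parameter column only through its
rank order, it is invariant under monotone transforms, and permuting the
parameter values is equivalent to randomly re-partitioning the outcomes
into bins -- so one shared set of permutation indices serves every
parameter column (a documented variance-reduction choice that makes the
null threshold per-experiment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import ExperimentSpec, experiment_catalog, run_all
from .model import SolverSettings
from .params import PARAM_NAMES, CoreParameters

__all__ = [
    "ParameterSample",
    "OutcomeMatrix",
    "SensitivityResult",
    "sample_parameters",
    "outcome_matrix",
    "sensitivity_measure",
    "binned_statistic_matrix",
    "permutation_filter",
    "normalize",
    "insensitive_parameters",
    "run_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterSample:
    """n sampled core-parameter sets (columns ordered as PARAM_NAMES)."""

    values: pd.DataFrame
    seed: int
    factor_range: tuple[float, float] = (0.5, 2.0)
    defaults: CoreParameters | None = None

    @property
    def n(self) -> int:
        return len(self.values)

    def parameters(self, row: int) -> CoreParameters:
        base = self.defaults or CoreParameters(**dict(self.values.iloc[row]))
        return base.replace(**{k: float(v) for k, v in self.values.iloc[row].items()})


@dataclass
class OutcomeMatrix:
    """n x 28 boolean outcomes; rows with solver failures are flagged."""

    outcomes: np.ndarray          # bool, n x n_experiments
    valid: np.ndarray             # bool, n (False where any experiment errored)
    experiment_ids: tuple[int, ...]

    @property
    def success_rates(self) -> np.ndarray:
        """Overall success rate f_i per experiment, over valid rows."""
        return self.outcomes[self.valid].mean(axis=0)


@dataclass
class SensitivityResult:
    sample: ParameterSample
    outcomes: OutcomeMatrix
    s: np.ndarray                 # n_experiments x n_parameters, raw
    thresholds: np.ndarray        # n_experiments (shared across parameters)
    filtered: np.ndarray          # s with sub-threshold entries zeroed
    normalized: np.ndarray        # filtered / row max (zero rows stay zero)
    n_bins: int
    n_permutations: int
    parameter_names: tuple[str, ...] = PARAM_NAMES

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.outcomes.experiment_ids, name="experiment")
        cols = list(self.parameter_names)
        return {
            "s_raw": pd.DataFrame(self.s, index=idx, columns=cols),
            "s_filtered": pd.DataFrame(self.filtered, index=idx, columns=cols),
            "s_normalized": pd.DataFrame(self.normalized, index=idx, columns=cols),
        }


def sample_parameters(
    defaults: CoreParameters,
    n: int,
    seed: int,
    factor_range: tuple[float, float] = (0.5, 2.0),
) -> ParameterSample:
    """Draw ``n`` parameter sets, log-uniform within ``factor_range`` x default.

    Each of the 30 core parameters is drawn independently; the conserved
    RSK1 total is not sampled.  A zero default is left at zero (a
    multiplicative range around zero is empty).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = factor_range
    if not (0 < lo <= hi):
        raise ValueError("factor_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    log_f = rng.uniform(np.log(lo), np.log(hi), size=(n, len(PARAM_NAMES)))
    base = np.array([getattr(defaults, p) for p in PARAM_NAMES])
    values = base[None, :] * np.exp(log_f)
    values[:, base == 0.0] = 0.0
    frame = pd.DataFrame(values, columns=list(PARAM_NAMES))
    return ParameterSample(frame, seed, (lo, hi), defaults)


def outcome_matrix(
    sample: ParameterSample,
    catalog: tuple[ExperimentSpec, ...] | None = None,
    settings: SolverSettings | None = None,
    progress: bool = False,
    n_jobs: int = 1,
) -> OutcomeMatrix:
    """Run the experiment battery for every sampled parameter set.

    Experiment-specific settings (the perturbations baked into the
    catalog) are never resampled -- only the core parameters vary.
    Rows where any experiment errors (solver failure) are excluded from
    success rates, with a logged count.
    """
    catalog = catalog or experiment_catalog()
    ids = tuple(spec.id for spec in catalog)
    # sampled parameter sets routinely push the linear MITF-activity map
    # negative; per-state warnings would flood a scan, so raise the bar
    logging.getLogger("pias3net.activity").setLevel(logging.ERROR)

    def one(row: int) -> tuple[np.ndarray, bool]:
        results = run_all(sample.parameters(row), settings, catalog)
        ok = np.array([results[i].passed for i in ids])
        valid = not any(results[i].errored for i in ids)
        return ok, valid

    rows = range(sample.n)
    if progress:
        from tqdm import tqdm

        rows = tqdm(rows, desc="parameter sets", total=sample.n)
    if n_jobs == 1:
        out = [one(r) for r in rows]
    else:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in rows)
    outcomes = np.array([o for o, _ in out], dtype=bool)
    valid = np.array([v for _, v in out], dtype=bool)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d of %d parameter sets had solver failures and are "
                       "excluded from success rates", n_bad, sample.n)
    return OutcomeMatrix(outcomes, valid, ids)


def sensitivity_measure(
    param_column: np.ndarray,
    outcome_column: np.ndarray,
    n_bins: int = 100,
) -> float:
    """Binned success-rate statistic s_ij for one (parameter, experiment) pair.

    Samples are sorted by the parameter (stable sort, so ties -- which
    have probability zero under continuous sampling -- break by sample
    index), split into ``n_bins`` equal bins, and the absolute deviations
    of the bin success rates from the overall rate are summed.
    """
    x = np.asarray(param_column, dtype=float)
    o = np.asarray(outcome_column, dtype=bool)
    n = len(x)
    if n != len(o):
        raise ValueError("parameter and outcome columns must have equal length")
    if n % n_bins != 0:
        raise ValueError(f"sample size {n} not divisible by n_bins={n_bins}")
    order = np.argsort(x, kind="stable")
    rates = o[order].reshape(n_bins, n // n_bins).mean(axis=1)
    return float(np.abs(rates - o.mean()).sum())


def binned_statistic_matrix(
    values: np.ndarray, outcomes: np.ndarray, n_bins: int
) -> np.ndarray:
    """s_ij for all experiments i and parameters j (vectorized)."""
    n, n_par = values.shape
    if n % n_bins != 0:
        raise ValueError(f"sample size {n} not divisible by n_bins={n_bins}")
    f = outcomes.mean(axis=0)  # per-experiment overall rate
    s = np.empty((outcomes.shape[1], n_par))
    for j in range(n_par):
        order = np.argsort(values[:, j], kind="stable")
        rates = outcomes[order].reshape(n_bins, n // n_bins, -1).mean(axis=1)
        s[:, j] = np.abs(rates - f[None, :]).sum(axis=0)
    return s


def permutation_filter(
    sample: ParameterSample,
    outcomes: OutcomeMatrix,
    s: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Null thresholds and the filtered statistic matrix.

    For each experiment the threshold is the maximum statistic observed
    when the parameter values are randomly permuted (one shared
    permutation stream across parameters; permuting parameter values is
    equivalent to randomly re-binning the outcomes, so the null does not
    depend on which parameter column is considered).  Entries at or below
    the threshold are zeroed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ok = outcomes.valid
    o = outcomes.outcomes[ok]
    n = o.shape[0]
    n_use = (n // n_bins) * n_bins
    o = o[:n_use]
    f = o.mean(axis=0)
    rng = np.random.default_rng(seed)
    thresholds = np.zeros(o.shape[1])
    for _ in range(n_permutations):
        perm = rng.permutation(n_use)
        rates = o[perm].reshape(n_bins, n_use // n_bins, -1).mean(axis=1)
        null_s = np.abs(rates - f[None, :]).sum(axis=0)
        thresholds = np.maximum(thresholds, null_s)
    filtered = np.where(s > thresholds[:, None], s, 0.0)
    return thresholds, filtered


def normalize(s: np.ndarray) -> np.ndarray:
    """Divide each experiment's row by its maximum; all-zero rows stay zero."""
    s = np.asarray(s, dtype=float)
    row_max = s.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_max > 0, s / row_max, 0.0)
    return out


def insensitive_parameters(
    filtered: np.ndarray, names: tuple[str, ...] = PARAM_NAMES
) -> set[str]:
    """Parameters whose filtered sensitivity is zero for every experiment."""
    zero_cols = np.all(filtered == 0.0, axis=0)
    return {names[j] for j in np.nonzero(zero_cols)[0]}


def run_sensitivity(
    defaults: CoreParameters,
    n: int = 10_000,
    n_bins: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
    catalog: tuple[ExperimentSpec, ...] | None = None,
    settings: SolverSettings | None = None,
    progress: bool = False,
    n_jobs: int = 1,
) -> SensitivityResult:
    """Full pipeline: sample, simulate, bin, permutation-filter, normalize."""
    sample = sample_parameters(defaults, n, seed)
    outcomes = outcome_matrix(sample, catalog, settings, progress, n_jobs)
    ok = outcomes.valid
    n_use = (int(ok.sum()) // n_bins) * n_bins
    values = sample.values.to_numpy()[ok][:n_use]
    o = outcomes.outcomes[ok][:n_use]
    s = binned_statistic_matrix(values, o, n_bins)
    # derive the permutation seed from the sampling seed, keeping both streams
    # reproducible yet distinct
    thresholds, filtered = permutation_filter(
        sample, outcomes, s, n_permutations, seed=seed + 1, n_bins=n_bins)
    return SensitivityResult(sample, outcomes, s, thresholds, filtered,
                             normalize(filtered), n_bins, n_permutations)
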