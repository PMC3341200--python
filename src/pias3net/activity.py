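"""Transcriptional-activity readouts.

Lab experiments on this network report luciferase reporter activity or
target-gene mRNA, not molecule counts.  Two mapping functions connect the
model state to those readouts:

* MITF activity -- a weighted sum over the four *free* phospho-forms
  (PIAS3-bound MITF is transcriptionally inactive), with weights fitted
  to reported mutant activities and a constant offset that keeps the
  luciferase analogue positive in practice;
* STAT3 activity -- the free phosphorylated STAT3 amount (PIAS3-bound
  phospho-STAT3 is blocked from DNA binding and excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import SIdx

__all__ = ["ActivityWeights", "DEFAULT_WEIGHTS", "mitf_activity", "stat3_activity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityWeights:
    """Weights of the linear MITF activity map (dimensionless).

    ``A0`` is a constant offset; ``A_M`` (unphosphorylated MITF) is
    slightly negative, so a large pool of unphosphorylated protein alone
    *lowers* reporter output, while the S73-bearing forms carry most of
    the transcriptional punch.
    """

    A0: float = 10.0
    A_M: float = -0.11
    A_M73: float = 0.44
    A_M409: float = 0.11
    A_Mpp: float = 0.56


DEFAULT_WEIGHTS = ActivityWeights()


def mitf_activity(state: np.ndarray, weights: ActivityWeights = DEFAULT_WEIGHTS) -> float:
    """MITF transcriptional activity of a model state.

    ``A0 + A_M*[MITF] + A_M73*[MITFp73] + A_M409*[MITFp409] + A_Mpp*[MITFpp]``
    over the free (non-complexed) species only.  The map is linear, so
    activity ratios between conditions are well defined on raw values;
    negative values are returned as computed (and logged), since the
    offset is an arbitrary-unit convention, not a floor.
    """
    y = np.asarray(state, dtype=float)
    f = (weights.A0
         + weights.A_M * y[SIdx.MITF]
         + weights.A_M73 * y[SIdx.MITFp73]
         + weights.A_M409 * y[SIdx.MITFp409]
         + weights.A_Mpp * y[SIdx.MITFpp])
    if f < 0:
        logger.warning("MITF activity is negative (%.4g); ratio-based criteria "
                       "may be unreliable for this state", f)
    return float(f)


def stat3_activity(state: np.ndarray) -> float:
    """STAT3 transcriptional activity: the free phospho-STAT3 amount."""
    return float(np.asarray(state, dtype=float)[SIdx.STAT3p])
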