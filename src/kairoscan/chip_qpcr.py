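"""ChIP-qPCR and sequential-ChIP (re-ChIP) arithmetic.

All quantities assume 100% amplification efficiency, i.e. one Cq cycle is
a twofold difference in DNA amount.

* percent input — IP recovery relative to the (dilution-adjusted) input
  chromatin: 100 * 2^((Cq_input - log2(1/input_fraction)) - Cq_IP).
* relative abundance — treated/mock ratio of percent inputs, reported per
  replicate against the mock mean so the replicate spread survives.
* sequential-ChIP efficiency — percent of first ChIP recovered by the
  second pull-down, computed as 100 * 2^(Cq_2nd - Cq_1st).  This is the
  printed convention of the assay; because more cycles mean less DNA it
  exceeds 100% when the second pull-down recovers less material.  The
  ``sign_corrected`` flag gives the physically decreasing form
  100 * 2^(Cq_1st - Cq_2nd).
* region significance — pooled-variance (Student) two-tailed t-test
  between replicate groups.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_INPUT_FRACTION = 0.01


def percent_input(
    cq_ip: float | np.ndarray,
    cq_input: float | np.ndarray,
    input_fraction: float = DEFAULT_INPUT_FRACTION,
) -> float | np.ndarray:
    """IP recovery as percent of input chromatin.

    The input Cq is first adjusted for the input dilution
    (Cq_input - log2(1/input_fraction)); each cycle the IP lies above the
    adjusted input halves the recovery.
    """
    if not (0 < input_fraction <= 1):
        raise InputError(f"input_fraction must be in (0, 1], got {input_fraction}")
    cq_ip = np.asarray(cq_ip, dtype=float)
    cq_input = np.asarray(cq_input, dtype=float)
    adjusted = cq_input - math.log2(1.0 / input_fraction)
    out = 100.0 * np.power(2.0, adjusted - cq_ip)
    return float(out) if out.ndim == 0 else out


def relative_abundance(
    percent_input_treated: Sequence[float],
    percent_input_mock: Sequence[float],
) -> np.ndarray:
    """Per-replicate treated/mock ratios of percent input.

    Each treated replicate is divided by the mock mean, retaining the
    treated replicate spread.  Scale-invariant: rescaling all percent
    inputs by a common factor leaves the ratios unchanged.
    """
    treated = np.asarray(percent_input_treated, dtype=float)
    mock = np.asarray(percent_input_mock, dtype=float)
    if treated.size == 0 or mock.size == 0:
        raise InputError("relative_abundance: empty replicate group")
    mock_mean = float(np.mean(mock))
    if mock_mean <= 0:
        raise ComputationError("relative_abundance: mock mean is not positive")
    return treated / mock_mean


def seqchip_efficiency(
    cq_first: float | np.ndarray,
    cq_second: float | np.ndarray,
    sign_corrected: bool = False,
) -> float | np.ndarray:
    """Percent of first ChIP recovered in the second pull-down.

    Default: 100 * 2^(Cq_2nd - Cq_1st) (the assay's printed convention).
    ``sign_corrected``: 100 * 2^(Cq_1st - Cq_2nd), which decreases as the
    second pull-down recovers less DNA.
    """
    cq_first = np.asarray(cq_first, dtype=float)
    cq_second = np.asarray(cq_second, dtype=float)
    delta = cq_first - cq_second if sign_corrected else cq_second - cq_first
    out = 100.0 * np.power(2.0, delta)
    return float(out) if out.ndim == 0 else out


def region_significance(
    values_ab: Sequence[float], values_noab: Sequence[float]
) -> tuple[float, float]:
    """Student (pooled-variance) two-tailed t-test between replicate groups.

    Returns (t, p).  Degenerate zero-variance groups: equal means give
    (0, 1); unequal means give (inf-signed t, 0) with a logged warning.
    """
    x = np.asarray(values_ab, dtype=float)
    y = np.asarray(values_noab, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InputError("region_significance: need >= 2 replicates per group")
    sx = float(np.var(x, ddof=1))
    sy = float(np.var(y, ddof=1))
    if sx == 0 and sy == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        logger.warning("region_significance: zero variance with unequal means; p=0")
        t = math.inf if np.mean(x) > np.mean(y) else -math.inf
        return t, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
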