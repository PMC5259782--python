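"""Replicate summaries and the paired two-tailed Student's t-test."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, DegenerateDataError


@dataclass
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    The SD of a single value is undefined and raises rather than
    returning 0 or NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DataError("mean of an empty sample is undefined")
    if arr.size < 2:
        raise DataError("sample SD needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def paired_t_test(x, y) -> PairedTestResult:
    """Paired two-tailed Student's t-test: t = d̄ / (s_d/√n), df = n-1.

    Zero-variance differences (including x == y) carry no information
    about spread and raise DegenerateDataError instead of fabricating a
    p-value of 0 or 1.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise DataError("paired samples must have equal length")
    n = xa.size
    if n < 2:
        raise DataError("paired t-test needs at least 2 pairs")
    d = xa - ya
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError(
            "zero-variance paired differences: t-test degenerate"
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t_statistic=t, df=n - 1, p_value=p)
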