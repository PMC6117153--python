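"""ROI summaries and paired comparisons for per-direction D* and tensor metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .signal_model import ParameterError

__all__ = ["ROIStats", "PairedTResult", "roi_mean", "roi_stats", "paired_t", "percent_change"]


class PairedTResult(NamedTuple):
    t: float
    p: float
    degenerate: bool  # zero variance of differences


@dataclass(frozen=True)
class ROIStats:
    """Across-subject summary of an ROI metric (SEM = sd / sqrt(n))."""

    roi_name: str
    n_subjects: int
    per_subject_means: tuple
    mean: float
    sem: float

    @classmethod
    def from_values(cls, roi_name: str, values: Sequence[float]) -> "ROIStats":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ParameterError("SEM requires at least 2 subjects")
        return cls(
            roi_name=roi_name,
            n_subjects=int(v.size),
            per_subject_means=tuple(v),
            mean=float(v.mean()),
            sem=float(v.std(ddof=1) / math.sqrt(v.size)),
        )


def roi_mean(
    values: np.ndarray, mask: np.ndarray, valid: Optional[np.ndarray] = None
) -> float:
    """Arithmetic mean of a scalar map over masked (and valid, finite) voxels."""
    mask = np.asarray(mask, dtype=bool)
    if valid is not None:
        mask = mask & np.asarray(valid, dtype=bool)
    vals = np.asarray(values, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ParameterError("ROI mask selects no valid voxels")
    return float(vals.mean())


def roi_stats(roi_name: str, per_subject_means: Sequence[float]) -> ROIStats:
    return ROIStats.from_values(roi_name, per_subject_means)


def paired_t(a: Sequence[float], b: Sequence[float], alternative: str = "two-sided") -> PairedTResult:
    """Classical paired t-test on per-subject values.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = a - b`` and n-1 degrees of
    freedom.  Zero difference variance is flagged degenerate (t = 0, p = 1
    when the means are also equal; otherwise the effect is infinitely
    certain under the model, t = +/-inf, p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be equal-length 1D sequences")
    n = a.size
    if n < 2:
        raise ParameterError("paired t-test requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        if m == 0:
            return PairedTResult(0.0, 1.0, True)
        return PairedTResult(math.copysign(math.inf, m), 0.0, True)
    t = m / (sd / math.sqrt(n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return PairedTResult(float(t), float(p), False)


def percent_change(baseline: float, post: float) -> float:
    """Percent change from baseline: ``100 * (post - baseline) / baseline``."""
    if baseline == 0:
        raise ParameterError("baseline must be non-zero")
    return 100.0 * (post - baseline) / baseline
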