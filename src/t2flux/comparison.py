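"""Bland-Altman agreement analysis between the two MRI contrast methods.

Paired tumor volumes — one from the T2 map, one from the T2 average image of
the same session — are compared by plotting their differences (map minus
average) against their means, with reference lines at the mean difference
plus/minus 1.96 sample standard deviations, and by a two-sided paired t-test
of the hypothesis that the mean difference is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "TTestResult", "bland_altman", "paired_t_test"]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    defined: bool


@dataclass
class AgreementResult:
    """Differences, limits of agreement, and the paired t-test.

    ``differences`` is map minus average per session; limits are
    ``mean_difference +- 1.96 * sd_difference`` with the sample (n-1) SD.
    ``t_defined`` is False when the differences have zero variance, in which
    case the limits collapse onto the mean.
    """

    differences: np.ndarray
    means: np.ndarray
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    t: float
    df: int
    p: float
    t_defined: bool

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.mean_difference <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean difference")
        if self.df != len(self.differences) - 1:
            raise ValueError("degrees of freedom must be n_pairs - 1")


def paired_t_test(differences: Sequence[float] | np.ndarray) -> TTestResult:
    """One-sample t-test of mean(differences) = 0, two-sided.

    t = mean / (sd / sqrt(n)) with the sample (n-1) SD and df = n - 1.
    Zero-variance differences yield an undefined-flag result, not an
    exception; fewer than 2 values raise.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError(f"need at least 2 differences, got {d.size}")
    n = d.size
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return TTestResult(math.nan, df, math.nan, False)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t, df, p, True)


def bland_altman(
    map_volumes: Sequence[float] | np.ndarray,
    average_volumes: Sequence[float] | np.ndarray,
) -> AgreementResult:
    """Agreement analysis of per-session volumes from the two contrast methods.

    Parameters
    ----------
    map_volumes, average_volumes:
        Tumor volumes (mm^3) from T2-map and T2-average contrast, paired by
        session, each of length >= 2.
    """
    vm = np.asarray(map_volumes, dtype=float)
    va = np.asarray(average_volumes, dtype=float)
    if vm.shape != va.shape or vm.ndim != 1:
        raise ValueError("paired volume lists must be 1-D and equal length")
    if vm.size < 2:
        raise ValueError(f"need at least 2 pairs, got {vm.size}")

    diffs = vm - va
    means = (vm + va) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    ttest = paired_t_test(diffs)
    return AgreementResult(
        differences=diffs,
        means=means,
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        t=ttest.t,
        df=ttest.df,
        p=ttest.p,
        t_defined=ttest.defined,
    )
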