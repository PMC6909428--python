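"""Mendelian segregation testing.

Pearson chi-square goodness of fit of observed phenotype class counts
against an expected ratio (e.g. 3:1 wild type : mutant for a monogenic
recessive F2). No continuity correction is applied: for the canonical
280-plant example (221 wild type, 59 mutant vs 3:1) the uncorrected test
gives p = 0.129 whereas the Yates-corrected one gives ≈ 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["SegregationTest", "chisq_segregation"]


@dataclass(frozen=True)
class SegregationTest:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    ratio: tuple[float, ...]
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "expected": list(self.expected),
            "ratio": list(self.ratio),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def chisq_segregation(
    observed: Sequence[int], ratio: Sequence[float]
) -> SegregationTest:
    """Test observed class counts against an expected segregation ratio.

    ``expected_i = total × weight_i / Σ weights``; the statistic is
    Σ (obs − exp)² / exp with df = classes − 1 and the p-value from the
    chi-square upper tail.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.shape != w.shape:
        raise ValueError("observed and ratio must be 1-D and the same length")
    if obs.size < 2:
        raise ValueError("need at least two phenotype classes")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if (w <= 0).any():
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * w / w.sum()
    if (expected == 0).any():
        raise ValueError("an expected count is zero")
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return SegregationTest(
        observed=tuple(int(x) for x in obs),
        expected=tuple(float(x) for x in expected),
        ratio=tuple(float(x) for x in w),
        statistic=float(statistic),
        df=obs.size - 1,
        p_value=float(p_value),
    )
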