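"""Replicate-level statistics and small assay helpers.

All condition comparisons in the pipeline run on biological-replicate
summaries (one value per replicate), with two-sided paired or Welch
(unequal-variance) t-tests.  Degenerate-variance cases are resolved
explicitly and flagged rather than returning NaN silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TTestOutcome:
    statistic: float
    pvalue: float
    degenerate: bool = False
    note: str = ""


def replicate_ttest(
    group_a, group_b, paired: bool = False
) -> TTestOutcome:
    """Two-sided t-test on replicate values.

    Paired tests require aligned replicate order.  Zero-variance cases:
    all-zero paired differences (or identical constant groups) carry no
    evidence, p = 1; constant nonzero differences are maximally
    significant, p = 0.  Both are flagged ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if paired:
        if a.size != b.size:
            raise ValueError(
                f"paired groups must align: {a.size} vs {b.size} replicates"
            )
        d = a - b
        if np.std(d, ddof=1) == 0.0:
            if np.all(d == 0.0):
                return TTestOutcome(0.0, 1.0, True, "all paired differences zero")
            return TTestOutcome(
                float("inf") if d[0] > 0 else float("-inf"),
                0.0,
                True,
                "constant nonzero paired differences",
            )
        res = sps.ttest_rel(a, b)
        return TTestOutcome(float(res.statistic), float(res.pvalue))
    if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
        same = a[0] == b[0]
        return TTestOutcome(
            0.0 if same else float("inf"),
            1.0 if same else 0.0,
            True,
            "both groups constant",
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestOutcome(float(res.statistic), float(res.pvalue))


def normalize_luciferase(luminescence, od600, abundance=1.0):
    """Luciferase activity normalized to cell density (OD600) and reporter
    protein abundance: luminescence / od600 / abundance.  Linear in the
    luminescence; denominators must be positive."""
    lum = np.asarray(luminescence, dtype=float)
    od = np.asarray(od600, dtype=float)
    ab = np.asarray(abundance, dtype=float)
    if np.any(od <= 0):
        raise ValueError("od600 must be > 0")
    if np.any(ab <= 0):
        raise ValueError("abundance must be > 0")
    out = lum / od / ab
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PetiteResult:
    fraction: float
    ci_low: float
    ci_high: float
    n_total: int


def petite_fraction(
    red_large: int, white_small: int, confidence: float = 0.95
) -> PetiteResult:
    """Respiration-deficient (petite) colony fraction with an exact
    Clopper-Pearson binomial confidence interval.

    ``red_large`` counts respiration-sufficient colonies, ``white_small``
    the petites; the fraction is white_small / total.
    """
    if red_large < 0 or white_small < 0:
        raise ValueError("colony counts must be >= 0")
    total = red_large + white_small
    if total == 0:
        raise ValueError("total colony count must be > 0")
    ci = sps.binomtest(white_small, total).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return PetiteResult(white_small / total, float(ci.low), float(ci.high), total)
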