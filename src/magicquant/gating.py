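"""Control-calibrated flow-cytometry gating and membrane-potential contrasts.

The positivity gate is calibrated on a vehicle-control sample: the threshold
is the (1 - target FPR) empirical quantile of the control spGFP
distribution, taken with "higher" interpolation, and positivity is strict
(>).  Together these guarantee that the realized control-positive fraction
never exceeds the target (default 1%), honouring the "less than 1% of
control cells positive" calibration rule for any finite sample.

Condition comparisons (e.g. mean TMRM of spGFP-positive vs -negative cells)
are made on biological-replicate summaries, never on pooled single cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import TTestOutcome, replicate_ttest


@dataclass(frozen=True)
class GateSpec:
    channel: str
    threshold: float
    target_control_fpr: float = 0.01
    control_condition_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_control_fpr < 1.0:
            raise ValueError("target_control_fpr must be in (0, 1)")


@dataclass(frozen=True)
class GateResult:
    condition_id: str | None
    n_events: int
    positive_fraction: float
    mean_tmrm_pos: float | None
    mean_tmrm_neg: float | None
    tmrm_negative_fraction: float | None = None


def calibrate_gate(
    control: pd.DataFrame,
    target_fpr: float = 0.01,
    channel: str = "spgfp",
    control_condition_id: str | None = None,
) -> GateSpec:
    """Set the positivity threshold from a control event table.

    The "higher"-interpolated (1 - target_fpr) quantile guarantees
    count(x > threshold) / n <= target_fpr for the control itself.  Controls
    smaller than 1/target_fpr events make the quantile unstable and trigger
    a warning.
    """
    if control.empty:
        raise ValueError("control event table is empty")
    values = np.asarray(control[channel], dtype=float)
    if len(values) < 1.0 / target_fpr:
        warnings.warn(
            f"control has {len(values)} events < 1/target_fpr = "
            f"{1.0 / target_fpr:.0f}; quantile is unstable",
            stacklevel=2,
        )
    threshold = float(np.quantile(values, 1.0 - target_fpr, method="higher"))
    return GateSpec(
        channel=channel,
        threshold=threshold,
        target_control_fpr=target_fpr,
        control_condition_id=control_condition_id,
    )


def apply_gate(
    events: pd.DataFrame,
    gate: GateSpec,
    tmrm_gate: GateSpec | None = None,
    condition_id: str | None = None,
) -> GateResult:
    """Fraction positive (strictly above threshold) and group TMRM means.

    ``tmrm_gate``, when supplied (calibrated the same way on an untreated
    control's TMRM distribution), adds the fraction of TMRM-negative events
    (tmrm below that gate's threshold).  Empty groups yield None means,
    never zero.
    """
    if gate.channel not in events.columns:
        raise KeyError(f"gate channel {gate.channel!r} not in event table")
    positive = events[gate.channel].to_numpy() > gate.threshold
    n = len(events)
    tmrm = events["tmrm"].to_numpy() if "tmrm" in events.columns else None

    def _mean(x: np.ndarray | None) -> float | None:
        if x is None or x.size == 0:
            return None
        return float(x.mean())

    tmrm_neg_frac = None
    if tmrm_gate is not None:
        if "tmrm" not in events.columns:
            raise KeyError("tmrm channel required for the TMRM-negative fraction")
        tmrm_neg_frac = float((events["tmrm"].to_numpy() < tmrm_gate.threshold).mean())

    return GateResult(
        condition_id=condition_id,
        n_events=n,
        positive_fraction=float(positive.mean()) if n else 0.0,
        mean_tmrm_pos=_mean(tmrm[positive]) if tmrm is not None else None,
        mean_tmrm_neg=_mean(tmrm[~positive]) if tmrm is not None else None,
        tmrm_negative_fraction=tmrm_neg_frac,
    )


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool,
) -> TTestOutcome:
    """Two-sided t-test on replicate-level summaries (one value per
    biological replicate; at least two, three for headline comparisons)."""
    return replicate_ttest(group_a, group_b, paired=paired)


def gate_results_to_frame(results: Sequence[GateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in results],
            "n_events": [r.n_events for r in results],
            "positive_fraction": [r.positive_fraction for r in results],
            "mean_tmrm_pos": [r.mean_tmrm_pos for r in results],
            "mean_tmrm_neg": [r.mean_tmrm_neg for r in results],
            "tmrm_negative_fraction": [r.tmrm_negative_fraction for r in results],
        }
    )
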