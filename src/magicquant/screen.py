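"""Two-stage hit calling for the genome-wide knockout reporter screen.

Stage 1 (flow): after subtracting a plate background from the population
mean spGFP of every strain, knockouts whose heat-shock/baseline fold change
is strictly below the cutoff (default 1.1) become candidates — they fail to
show the normal heat-shock increase in mitochondrial reporter signal.

Stage 2 (imaging): per-cell statistics classify each candidate.  A Class 1
mutant has an elevated spGFP/mCherry ratio at the permissive temperature
relative to wild type (two-sided per-cell test, P < 0.01); a Class 2 mutant
shows no significant per-cell spGFP change before vs after heat shock
(P > 0.01).  Strains on the exclusion list (known import-pathway genes) are
never called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import (
    CLASS1,
    CLASS2,
    CONDITION_30C,
    CONDITION_HS,
    EXCLUDED,
    ScreenPlateTruth,
)

NO_PHENOTYPE = "NO_PHENOTYPE"
LOW_SIGNAL = "LOW_SIGNAL"
INSUFFICIENT_CELLS = "INSUFFICIENT_CELLS"


@dataclass(frozen=True)
class StrainFlowSummary:
    strain_id: str
    mean_spgfp_30C: float
    mean_spgfp_HS: float
    background: float

    def __post_init__(self) -> None:
        if self.mean_spgfp_30C < 0 or self.mean_spgfp_HS < 0 or self.background < 0:
            raise ValueError("flow means and background must be >= 0")


@dataclass(frozen=True)
class HitCall:
    strain_id: str
    bg_sub_30C: float
    bg_sub_HS: float
    fold_change: float  # NaN when baseline signal is not positive
    is_candidate: bool
    annotations: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class MutantClassification:
    strain_id: str
    class_label: str
    p_class1: float  # NaN when not computed
    p_hs: float
    annotations: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ScreenConfig:
    """Screen thresholds and test choices.

    The fold cutoff and both alphas are the printed screen constants; the
    per-cell test is Welch's two-sided t by default (the study reports
    two-tailed t-tests throughout) and can be switched to Mann-Whitney.
    Benjamini-Hochberg adjustment across strains is available but off, to
    match per-strain thresholding.
    """

    fold_cutoff: float = 1.1
    alpha_class1: float = 0.01
    alpha_class2: float = 0.01
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    wt_strain_id: str = "WT"
    test: Literal["welch", "mannwhitney"] = "welch"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1.0:
            raise ValueError("fold_cutoff must be > 1")
        for a in (self.alpha_class1, self.alpha_class2):
            if not 0.0 < a < 1.0:
                raise ValueError("alphas must be in (0, 1)")


def call_candidates(
    summaries: Sequence[StrainFlowSummary], config: ScreenConfig = ScreenConfig()
) -> list[HitCall]:
    """Flow-based candidate filter: fold change strictly below the cutoff.

    Background-subtracted means define fold = HS / 30C.  Strains whose
    baseline signal is not positive cannot exhibit an increase and are
    flagged candidates-by-default with a LOW_SIGNAL annotation.
    """
    ids = [s.strain_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate strain_id(s): {dupes}")
    calls = []
    for s in summaries:
        b30 = s.mean_spgfp_30C - s.background
        bhs = s.mean_spgfp_HS - s.background
        if b30 > 0:
            fold = bhs / b30
            calls.append(
                HitCall(s.strain_id, b30, bhs, fold, fold < config.fold_cutoff)
            )
        else:
            calls.append(
                HitCall(s.strain_id, b30, bhs, float("nan"), True,
                        frozenset({LOW_SIGNAL}))
            )
    return calls


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided two-sample p-value; degenerate inputs resolved explicitly.

    Identical constant samples carry no evidence of a difference (p = 1);
    constant samples with different values are maximally different (p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if test == "welch":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mannwhitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


def _cells_of(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    return table[table["condition"] == condition]


def classify_mutant(
    ko_cells: pd.DataFrame,
    wt_cells: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> MutantClassification:
    """Classify one knockout from per-cell tables (columns: strain_id,
    condition, spgfp, mcherry).

    p_class1: per-cell spGFP/mCherry ratio, KO vs WT at 30 C (two-sided).
    p_hs: per-cell spGFP, 30 C vs heat shock within the KO (two-sided,
    unpaired — the compared cells are different individuals).
    Exclusion-listed strains are labelled EXCLUDED before any testing.
    """
    if ko_cells.empty or wt_cells.empty:
        raise ValueError("per-cell tables must be non-empty")
    sid = str(ko_cells["strain_id"].iloc[0])
    if ko_cells["strain_id"].nunique() != 1:
        raise ValueError("ko_cells mixes multiple strains")
    if sid in config.exclusion_list:
        return MutantClassification(sid, EXCLUDED, float("nan"), float("nan"))

    ko30 = _cells_of(ko_cells, CONDITION_30C)
    kohs = _cells_of(ko_cells, CONDITION_HS)
    wt30 = _cells_of(wt_cells, CONDITION_30C)
    if min(len(ko30), len(kohs), len(wt30)) < 2:
        return MutantClassification(
            sid, NO_PHENOTYPE, float("nan"), float("nan"),
            frozenset({INSUFFICIENT_CELLS}),
        )

    ko_ratio = (ko30["spgfp"] / ko30["mcherry"]).to_numpy()
    wt_ratio = (wt30["spgfp"] / wt30["mcherry"]).to_numpy()
    p_class1 = _two_sample_p(ko_ratio, wt_ratio, config.test)
    p_hs = _two_sample_p(
        ko30["spgfp"].to_numpy(), kohs["spgfp"].to_numpy(), config.test
    )

    if p_class1 < config.alpha_class1:
        label = CLASS1
    elif p_hs > config.alpha_class2:
        label = CLASS2
    else:
        label = NO_PHENOTYPE
    return MutantClassification(sid, label, p_class1, p_hs)


def classify_plate(
    cells: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> list[MutantClassification]:
    """Classify every knockout on a plate against the designated WT strain.

    With ``bh_correct`` enabled, Class 1 p-values are Benjamini-Hochberg
    adjusted across strains before thresholding.
    """
    wt_cells = cells[cells["strain_id"] == config.wt_strain_id]
    if wt_cells.empty:
        raise ValueError(f"wild-type strain {config.wt_strain_id!r} absent from plate")
    out = []
    for sid, ko_cells in cells.groupby("strain_id", sort=True):
        if sid == config.wt_strain_id:
            continue
        out.append(classify_mutant(ko_cells, wt_cells, config))
    if config.bh_correct:
        out = _bh_reclassify(out, config)
    return out


def _bh_reclassify(
    calls: list[MutantClassification], config: ScreenConfig
) -> list[MutantClassification]:
    tested = [c for c in calls if np.isfinite(c.p_class1)]
    if not tested:
        return calls
    adj = sps.false_discovery_control([c.p_class1 for c in tested])
    adj_map = {c.strain_id: q for c, q in zip(tested, adj)}
    out = []
    for c in calls:
        if c.strain_id not in adj_map or c.class_label == EXCLUDED:
            out.append(c)
            continue
        q = float(adj_map[c.strain_id])
        if q < config.alpha_class1:
            label = CLASS1
        elif c.p_hs > config.alpha_class2:
            label = CLASS2
        else:
            label = NO_PHENOTYPE
        out.append(MutantClassification(c.strain_id, label, q, c.p_hs, c.annotations))
    return out


@dataclass(frozen=True)
class ScreenEvaluation:
    confusion: pd.DataFrame  # rows = truth, columns = called
    sensitivity: dict[str, float]  # per planted class
    specificity: float  # fraction of true nulls not called


def evaluate_screen(
    classifications: Iterable[MutantClassification],
    truth: Sequence[ScreenPlateTruth],
) -> ScreenEvaluation:
    """Confusion matrix and per-class recovery against planted truth."""
    truth_map = {t.strain_id: t.true_class for t in truth}
    calls = list(classifications)
    unknown = sorted({c.strain_id for c in calls} - truth_map.keys())
    if unknown:
        raise KeyError(f"strain id(s) absent from truth: {unknown}")
    rows = pd.DataFrame(
        {
            "truth": [truth_map[c.strain_id] for c in calls],
            "called": [c.class_label for c in calls],
        }
    )
    confusion = pd.crosstab(rows["truth"], rows["called"])
    sensitivity = {}
    for cls in (CLASS1, CLASS2):
        mask = rows["truth"] == cls
        if mask.any():
            sensitivity[cls] = float((rows.loc[mask, "called"] == cls).mean())
    null_mask = rows["truth"] == "NULL"
    specificity = (
        float((rows.loc[null_mask, "called"] == NO_PHENOTYPE).mean())
        if null_mask.any()
        else float("nan")
    )
    return ScreenEvaluation(confusion, sensitivity, specificity)


def calls_to_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [c.strain_id for c in calls],
            "bg_sub_30C": [c.bg_sub_30C for c in calls],
            "bg_sub_HS": [c.bg_sub_HS for c in calls],
            "fold_change": [c.fold_change for c in calls],
            "is_candidate": [c.is_candidate for c in calls],
            "annotations": ["|".join(sorted(c.annotations)) for c in calls],
        }
    )


def classifications_to_frame(calls: Sequence[MutantClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [c.strain_id for c in calls],
            "class_label": [c.class_label for c in calls],
            "p_class1": [c.p_class1 for c in calls],
            "p_hs": [c.p_hs for c in calls],
            "annotations": ["|".join(sorted(c.annotations)) for c in calls],
        }
    )


def summaries_from_frame(df: pd.DataFrame) -> list[StrainFlowSummary]:
    """Build StrainFlowSummary records from a table with columns
    strain_id, mean_spgfp_30C, mean_spgfp_HS, background."""
    return [
        StrainFlowSummary(
            strain_id=str(r.strain_id),
            mean_spgfp_30C=float(r.mean_spgfp_30C),
            mean_spgfp_HS=float(r.mean_spgfp_HS),
            background=float(r.background),
        )
        for r in df.itertuples(index=False)
    ]
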