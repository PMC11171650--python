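"""Diagnosis grouping, comparative statistics, ROC curves and the two-stage
FD decision rule.

A lesion record is (id, histopathological diagnosis, fractal dimension).  The
twelve-label diagnosis vocabulary is closed; three grouping schemes coarsen it:

* ``benign_malignant`` — benign = {nevus, verrucous lesion, neurofibroma,
  vascular lesion}; everything else (melanomas, Breslow-graded lesions,
  atypical melanocytic proliferation, basal and squamous cell carcinoma) is
  malignant.  Squamous cell carcinoma is malignant by default; pass
  ``scc_malignant=False`` to move it to benign.
* ``melanoma_nonmelanoma`` — melanoma = {non-metastatic melanoma, metastatic
  melanoma, Breslow 1/2/3}; all other diagnoses are non-melanoma.
* ``metastatic_nonmetastatic`` — defined over the melanoma group only.

The decision rule screens a lesion by its FD alone: stage 1 calls it
malignant iff FD > t_malignant; a malignant call proceeds to stage 2, which
calls melanoma iff FD > t_melanoma (strictly greater in both stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, VocabularyError

#: The closed histopathological vocabulary.
VOCABULARY: tuple[str, ...] = (
    "non-metastatic melanoma",
    "metastatic melanoma",
    "atypical melanocytic proliferation",
    "nevus",
    "verrucous lesion",
    "vascular lesion",
    "squamous cell carcinoma",
    "neurofibroma",
    "basal cell carcinoma",
    "Breslow 1",
    "Breslow 2",
    "Breslow 3",
)

BENIGN_DIAGNOSES = frozenset(
    {"nevus", "verrucous lesion", "vascular lesion", "neurofibroma"}
)
MELANOMA_DIAGNOSES = frozenset(
    {
        "non-metastatic melanoma",
        "metastatic melanoma",
        "Breslow 1",
        "Breslow 2",
        "Breslow 3",
    }
)

#: Default stage-1 cutoff: the malignant-group median FD.
DEFAULT_T_MALIGNANT = 1.74
#: Default stage-2 cutoff: the melanoma-group median FD.
DEFAULT_T_MELANOMA = 1.755


@dataclass(frozen=True)
class LesionRecord:
    """(id, diagnosis, fractal dimension) — the row unit of every stage."""

    id: str
    diagnosis: str
    fd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fd < 2.1:
            raise ValueError(f"fd {self.fd} outside (0, 2.1)")


@dataclass(frozen=True)
class GroupingScheme:
    name: str
    mapping: dict[str, str]

    def group_of(self, diagnosis: str) -> str:
        try:
            return self.mapping[diagnosis]
        except KeyError:
            raise VocabularyError(
                f"diagnosis {diagnosis!r} not in scheme {self.name!r}"
            ) from None


def get_scheme(name: str, scc_malignant: bool = True) -> GroupingScheme:
    """Return one of the predefined grouping schemes by name."""
    if name == "benign_malignant":
        benign = set(BENIGN_DIAGNOSES)
        if not scc_malignant:
            benign.add("squamous cell carcinoma")
        mapping = {
            d: ("benign" if d in benign else "malignant") for d in VOCABULARY
        }
    elif name == "melanoma_nonmelanoma":
        mapping = {
            d: ("melanoma" if d in MELANOMA_DIAGNOSES else "non-melanoma")
            for d in VOCABULARY
        }
    elif name == "metastatic_nonmetastatic":
        mapping = {
            d: ("metastatic" if d == "metastatic melanoma" else "non-metastatic")
            for d in sorted(MELANOMA_DIAGNOSES)
        }
    else:
        raise ValueError(f"unknown grouping scheme {name!r}")
    return GroupingScheme(name, mapping)


def assign_groups(
    records: list[LesionRecord], scheme: GroupingScheme
) -> list[tuple[LesionRecord, str]]:
    """Deterministically label every record with its group under ``scheme``."""
    return [(r, scheme.group_of(r.diagnosis)) for r in records]


def group_counts(records: list[LesionRecord], scheme: GroupingScheme) -> pd.Series:
    """Per-group record counts (sum equals the cohort size)."""
    labels = [g for _, g in assign_groups(records, scheme)]
    return pd.Series(labels, dtype="object").value_counts().sort_index()


def median_ci(values: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    alpha = 1.0 - conf
    lo = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi = int(stats.binom.isf(alpha / 2, n, 0.5))
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    return float(x[lo]), float(x[hi])


def _dunn_pairwise(
    groups: dict[str, np.ndarray], reference: str
) -> pd.DataFrame:
    """Dunn's rank-sum z comparisons of every group against ``reference``,
    with the usual tie correction and Bonferroni adjustment."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction: sum over tie groups of (t^3 - t)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    mean_ranks, offset = {}, 0
    for g in names:
        n_g = groups[g].size
        mean_ranks[g] = float(ranks[offset : offset + n_g].mean())
        offset += n_g
    rows = []
    others = [g for g in names if g != reference]
    for g in others:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / groups[g].size + 1.0 / groups[reference].size)
        )
        z = (mean_ranks[g] - mean_ranks[reference]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "comparison": f"{g} vs {reference}",
                "z": z,
                "p_raw": p,
                "p_adj": min(1.0, p * len(others)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Results of a between-group FD comparison."""

    test_name: str
    statistic: float
    pvalue: float
    group_summary: pd.DataFrame  # group, n, median, ci_low, ci_high
    pairwise: pd.DataFrame | None = None  # Dunn comparisons (>2 groups)

    def summary(self) -> str:
        lines = [
            f"{self.test_name}: statistic = {self.statistic:.4f}, "
            f"p = {self.pvalue:.3g}",
            self.group_summary.to_string(index=False),
        ]
        if self.pairwise is not None and len(self.pairwise):
            lines.append("Dunn pairwise (Bonferroni-adjusted):")
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def compare_groups(
    records: list[LesionRecord],
    scheme: GroupingScheme,
    reference: str | None = None,
) -> GroupComparison:
    """Mann–Whitney U (two groups) or Kruskal–Wallis + Dunn (more).

    Every group must contribute at least two records.  Medians carry 95%
    order-statistic confidence intervals.  For more than two groups, Dunn's
    pairwise comparisons are run against ``reference`` (default: the largest
    group).
    """
    by_group: dict[str, list[float]] = {}
    for rec, grp in assign_groups(records, scheme):
        by_group.setdefault(grp, []).append(rec.fd)
    groups = {g: np.asarray(v, dtype=float) for g, v in sorted(by_group.items())}
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 non-empty groups, got {len(groups)}"
        )
    for g, v in groups.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {g!r} has {v.size} record(s)")

    summary = pd.DataFrame(
        [
            {
                "group": g,
                "n": v.size,
                "median": float(np.median(v)),
                "ci_low": median_ci(v)[0],
                "ci_high": median_ci(v)[1],
            }
            for g, v in groups.items()
        ]
    )
    values = list(groups.values())
    if len(groups) == 2:
        res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
        return GroupComparison(
            "Mann-Whitney U", float(res.statistic), float(res.pvalue), summary
        )
    kw = stats.kruskal(*values)
    if reference is None:
        reference = max(groups, key=lambda g: groups[g].size)
    elif reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    pairwise = _dunn_pairwise(groups, reference)
    return GroupComparison(
        "Kruskal-Wallis", float(kw.statistic), float(kw.pvalue), summary, pairwise
    )


@dataclass
class RocCurve:
    """Threshold sweep of the rule "positive iff FD > t"."""

    points: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float  # trapezoidal area under the ROC curve
    auc_u: float  # Mann-Whitney U / (n_pos * n_neg); equals auc
    positive_label: str

    def operating_point(self, threshold: float) -> tuple[float, float]:
        """(sensitivity, specificity) at the sweep point nearest threshold."""
        idx = (self.points["threshold"] - threshold).abs().idxmin()
        row = self.points.loc[idx]
        return float(row["sensitivity"]), float(row["specificity"])


def roc_curve(
    records: list[LesionRecord], scheme: GroupingScheme, positive: str
) -> RocCurve:
    """ROC of FD as a score for membership in the ``positive`` group.

    Thresholds sweep the sorted distinct FD values with a strictly-greater
    classification rule; the trapezoidal AUC is cross-checked against the
    Mann-Whitney identity AUC = U / (n_pos * n_neg).
    """
    pos, neg = [], []
    for rec, grp in assign_groups(records, scheme):
        (pos if grp == positive else neg).append(rec.fd)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty for a ROC curve")
    pos_a, neg_a = np.asarray(pos), np.asarray(neg)
    thresholds = np.unique(np.concatenate([pos_a, neg_a]))
    sens = np.array([(pos_a > t).mean() for t in thresholds])
    spec = np.array([(neg_a <= t).mean() for t in thresholds])
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    # sweep from "call everything positive" to "call nothing positive"
    fpr = np.concatenate([[1.0], 1.0 - spec])
    tpr = np.concatenate([[1.0], sens])
    order = np.lexsort((tpr, fpr))  # tied FPRs enter at the lower TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    u = stats.mannwhitneyu(pos_a, neg_a, alternative="two-sided").statistic
    auc_u = float(u) / (pos_a.size * neg_a.size)
    return RocCurve(points, auc, auc_u, positive)


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of the two-stage FD screen for one lesion."""

    id: str | None
    stage1: str  # "benign" | "malignant"
    stage2: str | None  # "melanoma" | "non-melanoma" | None
    thresholds_used: tuple[float, float]


def decide(
    fd: float,
    t_malignant: float = DEFAULT_T_MALIGNANT,
    t_melanoma: float = DEFAULT_T_MELANOMA,
    id: str | None = None,
) -> DecisionResult:
    """Two-stage FD decision rule (strict inequalities at both stages)."""
    if not 0.0 < fd < 2.1:
        raise ValueError(f"fd {fd} outside (0, 2.1)")
    if fd > t_malignant:
        stage2 = "melanoma" if fd > t_melanoma else "non-melanoma"
        return DecisionResult(id, "malignant", stage2, (t_malignant, t_melanoma))
    return DecisionResult(id, "benign", None, (t_malignant, t_melanoma))


@dataclass
class StageConfusion:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class ScreenReport:
    """Confusion summary of the two-stage screen against true diagnoses."""

    stage1: StageConfusion
    stage2: StageConfusion | None
    decisions: list[DecisionResult]
    thresholds_used: tuple[float, float]

    def summary(self) -> str:
        t1, t2 = self.thresholds_used
        lines = [
            f"Stage 1 (malignant iff FD > {t1}): "
            f"sens {self.stage1.sensitivity:.3f}, spec {self.stage1.specificity:.3f} "
            f"(tp {self.stage1.tp}, fp {self.stage1.fp}, "
            f"tn {self.stage1.tn}, fn {self.stage1.fn})"
        ]
        if self.stage2 is not None:
            lines.append(
                f"Stage 2 (melanoma iff FD > {t2}): "
                f"sens {self.stage2.sensitivity:.3f}, "
                f"spec {self.stage2.specificity:.3f} "
                f"(tp {self.stage2.tp}, fp {self.stage2.fp}, "
                f"tn {self.stage2.tn}, fn {self.stage2.fn})"
            )
        return "\n".join(lines)


def _confusion(pred_pos: np.ndarray, truth_pos: np.ndarray) -> StageConfusion:
    tp = int(np.sum(pred_pos & truth_pos))
    fp = int(np.sum(pred_pos & ~truth_pos))
    tn = int(np.sum(~pred_pos & ~truth_pos))
    fn = int(np.sum(~pred_pos & truth_pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return StageConfusion(sens, spec, tp, fp, tn, fn)


def screen_cohort(
    records: list[LesionRecord],
    t_malignant: float = DEFAULT_T_MALIGNANT,
    t_melanoma: float = DEFAULT_T_MELANOMA,
) -> ScreenReport:
    """Apply the two-stage decision rule to a labelled cohort.

    Stage-1 sensitivity/specificity is measured against the benign/malignant
    grouping of the true diagnoses; stage 2 is evaluated on the records the
    screen sent forward (predicted malignant), against the melanoma /
    non-melanoma grouping.
    """
    if not records:
        raise InsufficientDataError("empty cohort")
    bm = get_scheme("benign_malignant")
    mnm = get_scheme("melanoma_nonmelanoma")
    decisions = [decide(r.fd, t_malignant, t_melanoma, id=r.id) for r in records]
    pred_mal = np.array([d.stage1 == "malignant" for d in decisions])
    truth_mal = np.array([bm.group_of(r.diagnosis) == "malignant" for r in records])
    stage1 = _confusion(pred_mal, truth_mal)
    stage2 = None
    if pred_mal.any():
        fwd = pred_mal
        pred_mel = np.array(
            [d.stage2 == "melanoma" for d in decisions], dtype=bool
        )[fwd]
        truth_mel = np.array(
            [mnm.group_of(r.diagnosis) == "melanoma" for r in records]
        )[fwd]
        stage2 = _confusion(pred_mel, truth_mel)
    return ScreenReport(stage1, stage2, decisions, (t_malignant, t_melanoma))
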