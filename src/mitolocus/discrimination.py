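"""Threshold-based species discrimination from pairwise distances.

Every unordered pair of samples is labelled same-species or
different-species (after collapsing named subspecies onto their species).
A pair whose distance falls strictly below a threshold is called positive
(same species predicted).  The resulting two-by-two contingency table

                     same species (A)   different species (a)
    < threshold (B)        n_AB                 n_aB
    > threshold (b)        n_Ab                 n_ab

yields the false-positive rate n_aB/n_a, false-negative rate n_Ab/n_A,
sensitivity n_AB/n_A, specificity n_ab/n_a, positive predictive value
n_AB/n_B and negative predictive value n_ab/n_b.

The ROC curve sweeps the threshold over all observed distances (smaller
values indicating a positive result) and the AUC equals the Mann–Whitney
U-statistic with ties counted one half; its standard error follows
Hanley & McNeil's non-parametric formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .alignment_io import TaxonomyTable
from .distances import DistanceMatrix
from .errors import InputError

__all__ = [
    "LabeledPair",
    "ContingencyTable",
    "DiscriminationMetrics",
    "ROCCurve",
    "GapReport",
    "label_pairs",
    "contingency",
    "metrics",
    "metrics_from_counts",
    "gap_scan",
    "roc",
    "deduplicate_sequences",
    "DEFAULT_THRESHOLDS",
]

#: Candidate K2P (x100) thresholds bracketing the barcoding gap.
DEFAULT_THRESHOLDS = (1.5, 2.0, 2.5)


@dataclass(frozen=True)
class LabeledPair:
    id1: str
    id2: str
    distance: float  # on the x100 reporting scale
    same_species: bool


@dataclass(frozen=True)
class ContingencyTable:
    """Two-by-two table of threshold calls against species identity."""

    n_ab_tp: int  # n_AB, true positives
    n_fp: int  # n_aB, false positives
    n_fn: int  # n_Ab, false negatives
    n_tn: int  # n_ab, true negatives
    threshold: float

    @property
    def n_same(self) -> int:  # n_A
        return self.n_ab_tp + self.n_fn

    @property
    def n_diff(self) -> int:  # n_a
        return self.n_fp + self.n_tn

    @property
    def n_positive(self) -> int:  # n_B
        return self.n_ab_tp + self.n_fp

    @property
    def n_negative(self) -> int:  # n_b
        return self.n_fn + self.n_tn

    @property
    def n_total(self) -> int:
        return self.n_same + self.n_diff

    def as_dict(self) -> dict[str, float]:
        return {
            "threshold": self.threshold,
            "n_AB": self.n_ab_tp,
            "n_aB": self.n_fp,
            "n_Ab": self.n_fn,
            "n_ab": self.n_tn,
            "n_A": self.n_same,
            "n_a": self.n_diff,
            "n_B": self.n_positive,
            "n_b": self.n_negative,
            "n": self.n_total,
        }


@dataclass(frozen=True)
class DiscriminationMetrics:
    """Derived rates; a component is None when its denominator is zero."""

    fp_rate: float | None
    fn_rate: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class ROCCurve:
    points: np.ndarray  # rows of (1 - specificity, sensitivity)
    auc: float
    auc_se: float


@dataclass(frozen=True)
class GapReport:
    """Barcoding-gap summary: the empty interval (if any) between the
    largest same-species and smallest different-species distance."""

    max_intra: float
    min_inter: float
    gap_interval: tuple[float, float] | None
    candidate_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    histogram: dict = field(default=None, hash=False)  # type: ignore[assignment]


def label_pairs(
    matrix: DistanceMatrix, taxonomy: TaxonomyTable
) -> list[LabeledPair]:
    """Label every unordered finite pair by collapsed species identity."""
    ids = matrix.sample_ids
    species = {sid: taxonomy.species_of(sid) for sid in ids}
    scaled = matrix.values * 100.0  # pair labels always use the x100 scale
    pairs: list[LabeledPair] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if matrix.saturated[i, j]:
                continue
            pairs.append(
                LabeledPair(
                    ids[i],
                    ids[j],
                    float(scaled[i, j]),
                    species[ids[i]] == species[ids[j]],
                )
            )
    return pairs


def contingency(
    pairs: Sequence[LabeledPair], threshold: float, strict: bool = True
) -> ContingencyTable:
    """Tabulate pairs against a distance threshold.

    ``strict`` (the default) counts a pair positive iff distance < threshold;
    a pair exactly at the threshold is negative.
    """
    if not pairs:
        raise InputError("no pairs to tabulate")
    tp = fp = fn = tn = 0
    for pair in pairs:
        positive = (
            pair.distance < threshold if strict else pair.distance <= threshold
        )
        if pair.same_species:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ContingencyTable(tp, fp, fn, tn, threshold)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(table: ContingencyTable) -> DiscriminationMetrics:
    """Derived discrimination metrics from a contingency table."""
    return DiscriminationMetrics(
        fp_rate=_ratio(table.n_fp, table.n_diff),
        fn_rate=_ratio(table.n_fn, table.n_same),
        sensitivity=_ratio(table.n_ab_tp, table.n_same),
        specificity=_ratio(table.n_tn, table.n_diff),
        ppv=_ratio(table.n_ab_tp, table.n_positive),
        npv=_ratio(table.n_tn, table.n_negative),
    )


def metrics_from_counts(
    n_aB: int, n_Ab: int, n_B: int, n_b: int, threshold: float = 0.0
) -> DiscriminationMetrics:
    """Metrics from the marginal/cell counts usually reported in print:
    false positives, false negatives, and the positive/negative totals."""
    table = ContingencyTable(
        n_ab_tp=n_B - n_aB, n_fp=n_aB, n_fn=n_Ab, n_tn=n_b - n_Ab, threshold=threshold
    )
    return metrics(table)


def gap_scan(
    pairs: Sequence[LabeledPair],
    candidate_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    bin_width: float = 0.1,
) -> GapReport:
    """Locate the barcoding gap and build a distance histogram."""
    intra = [p.distance for p in pairs if p.same_species]
    inter = [p.distance for p in pairs if not p.same_species]
    if not intra or not inter:
        raise InputError("need at least one pair in each class")
    max_intra, min_inter = max(intra), min(inter)
    gap = (max_intra, min_inter) if max_intra < min_inter else None
    all_d = np.array([p.distance for p in pairs])
    edges = np.arange(0.0, all_d.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    hist = {
        "bin_edges": edges,
        "intra_counts": np.histogram(intra, bins=edges)[0],
        "inter_counts": np.histogram(inter, bins=edges)[0],
    }
    return GapReport(max_intra, min_inter, gap, tuple(candidate_thresholds), hist)


def roc(pairs: Sequence[LabeledPair]) -> ROCCurve:
    """ROC curve and AUC over all observed distance thresholds.

    Smaller distances indicate a positive (same-species) call.  The
    trapezoid AUC equals U/(n_A * n_a) with ties counted one half.
    """
    same = np.array([p.distance for p in pairs if p.same_species])
    diff = np.array([p.distance for p in pairs if not p.same_species])
    if same.size == 0 or diff.size == 0:
        raise InputError("ROC needs both classes present")
    # sweep: at threshold t (strict <), TPR = frac(same < t), FPR = frac(diff < t)
    thresholds = np.unique(np.concatenate([same, diff]))
    cut = np.concatenate([thresholds, [np.inf]])
    tpr = np.searchsorted(np.sort(same), cut, side="left") / same.size
    fpr = np.searchsorted(np.sort(diff), cut, side="left") / diff.size
    points = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    # Mann-Whitney AUC with half ties, via midranks; U_same counts
    # (same, diff) pairs with d_same > d_diff (+ half per tie)
    n_a, n_n = same.size, diff.size
    ranks = rankdata(np.concatenate([same, diff]))
    u_same = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    # smaller distance = positive, so AUC = P(d_same < d_diff) + 0.5 P(tie)
    auc = float(1.0 - u_same / (n_a * n_n))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_a - 1) * (q1 - auc**2)
        + (n_n - 1) * (q2 - auc**2)
    ) / (n_a * n_n)
    return ROCCurve(points, auc, float(np.sqrt(max(var, 0.0))))


def deduplicate_sequences(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop records whose gene sequence exactly duplicates an earlier one."""
    seen: set[str] = set()
    out = []
    for sid, seq in records:
        if seq not in seen:
            seen.add(seq)
            out.append((sid, seq))
    return out
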