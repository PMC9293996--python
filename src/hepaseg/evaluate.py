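"""Segmentation and detection scoring against multiple raters.

Segmentation quality is the Dice score against each rater plus an
uncertainty-aware score

    phi = max(1 - alpha * eps_hat / eps_bar, 0)

where ``eps_hat = 1 - mean Dice(algorithm, rater)`` is the algorithm's mean
discrepancy and ``eps_bar = 1 - mean pairwise Dice(rater_i, rater_j)`` the
inter-rater discrepancy. With alpha = 0.1, phi >= 0.9 means the automatic
segmentation is as good as a human rater given the observed inter-rater
disagreement; phi = 1 is perfect agreement with every rater.

Detection quality tolerates split and merged lesion instances: connected
lesion components (6-neighborhood) of the reference and predicted masks are
clustered into N:M correspondences chosen to maximize the mean
per-correspondence Dice (computed on the union of member components;
components left unmatched count as zero-Dice singletons in the objective).
A correspondence with Dice above 0.2 counts as one true positive, otherwise
as one false positive plus one false negative; unmatched reference /
predicted components count as false negatives / false positives. Recall,
precision, F1 and false positives per case (FPC) follow from these counts.

Statistical comparisons between algorithms use the two-sided Wilcoxon
signed-rank test with Benjamini-Hochberg correction across the comparison
family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .config import ScoreConfig
from .phantom import STRUCT_6
from .volume import MaskVolume

log = logging.getLogger("hepaseg")


# ------------------------------------------------------------ overlap scores

def dice(a: MaskVolume | np.ndarray, b: MaskVolume | np.ndarray) -> float:
    """Dice score 2|A∩B| / (|A|+|B|); 1 when both masks are empty."""
    da = a.data if isinstance(a, MaskVolume) else np.asarray(a)
    db = b.data if isinstance(b, MaskVolume) else np.asarray(b)
    if isinstance(a, MaskVolume) and isinstance(b, MaskVolume):
        a.check_same_grid(b)
    elif da.shape != db.shape:
        raise ValueError("shape mismatch")
    pa, pb = da > 0, db > 0
    total = int(pa.sum()) + int(pb.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / total


def uncertainty_aware_score(mean_algo_dice: float, mean_rater_dice: float,
                            alpha: float = 0.1) -> float:
    """phi = max(1 - alpha * (1 - mean_algo_dice) / (1 - mean_rater_dice), 0).

    Raises ``ValueError`` when the raters agree perfectly (the inter-rater
    discrepancy is zero and the score is undefined).
    """
    eps_bar = 1.0 - mean_rater_dice
    if eps_bar <= 0.0:
        raise ValueError("perfect rater agreement: uncertainty-aware score undefined")
    eps_hat = 1.0 - mean_algo_dice
    return max(1.0 - alpha * eps_hat / eps_bar, 0.0)


# ------------------------------------------------------- lesion correspondence

def label_lesions(m: MaskVolume | np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components under 6-connectivity, labelled 1..k in scan order."""
    data = m.data if isinstance(m, MaskVolume) else np.asarray(m)
    labels, n = ndimage.label(data > 0, structure=STRUCT_6)
    return labels, int(n)


@dataclass(frozen=True)
class Correspondence:
    """One N:M matched group with its per-correspondence Dice."""

    ref_ids: tuple[int, ...]
    pred_ids: tuple[int, ...]
    dice: float


@dataclass
class CorrespondenceSet:
    """Partition of lesion components into matched groups and unmatched ids."""

    correspondences: list[Correspondence]
    unmatched_ref: list[int]
    unmatched_pred: list[int]
    n_ref: int = 0
    n_pred: int = 0

    def mean_dice(self) -> float:
        """Mean per-group Dice including unmatched components as 0 (the
        objective the matching maximizes); 1.0 for two empty masks."""
        vals = [c.dice for c in self.correspondences]
        vals += [0.0] * (len(self.unmatched_ref) + len(self.unmatched_pred))
        return float(np.mean(vals)) if vals else 1.0


class _Overlap:
    """Pairwise overlap statistics between labelled component sets."""

    def __init__(self, ref_labels: np.ndarray, n_ref: int,
                 pred_labels: np.ndarray, n_pred: int) -> None:
        self.n_ref, self.n_pred = n_ref, n_pred
        self.ref_sizes = np.bincount(ref_labels.ravel(), minlength=n_ref + 1)[1:]
        self.pred_sizes = np.bincount(pred_labels.ravel(), minlength=n_pred + 1)[1:]
        both = (ref_labels > 0) & (pred_labels > 0)
        pairs = ref_labels[both] * (n_pred + 1) + pred_labels[both]
        counts = np.bincount(pairs, minlength=(n_ref + 1) * (n_pred + 1))
        self.overlap = counts.reshape(n_ref + 1, n_pred + 1)[1:, 1:]
        self.edges = [(int(i), int(j)) for i, j in np.argwhere(self.overlap > 0)]

    def group_dice(self, ref_ids, pred_ids) -> float:
        ov = self.overlap[np.ix_(list(ref_ids), list(pred_ids))].sum() if ref_ids and pred_ids else 0
        size = self.ref_sizes[list(ref_ids)].sum() + self.pred_sizes[list(pred_ids)].sum()
        return 2.0 * float(ov) / float(size) if size else 1.0

    def objective(self, edges: list[tuple[int, int]]) -> float:
        """Mean per-group Dice over all components, given the kept edges."""
        groups = _connected_groups(self.n_ref, self.n_pred, edges)
        vals = [self.group_dice(r, p) for r, p in groups]
        return float(np.mean(vals)) if vals else 1.0


def _connected_groups(n_ref: int, n_pred: int, edges: list[tuple[int, int]]
                      ) -> list[tuple[list[int], list[int]]]:
    """Connected components of the bipartite graph (singletons included)."""
    parent = list(range(n_ref + n_pred))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ra, rb = find(i), find(n_ref + j)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, tuple[list[int], list[int]]] = {}
    for node in range(n_ref + n_pred):
        root = find(node)
        g = groups.setdefault(root, ([], []))
        if node < n_ref:
            g[0].append(node)
        else:
            g[1].append(node - n_ref)
    return list(groups.values())


def match_lesions(ref: MaskVolume, pred: MaskVolume,
                  cfg: ScoreConfig | None = None) -> CorrespondenceSet:
    """Cluster reference and predicted lesions into N:M correspondences.

    Starts from the full bipartite overlap graph (initial correspondences =
    its connected components) and greedily removes the overlap edge whose
    removal most increases the mean per-correspondence Dice, until no single
    removal improves it. Components with no remaining connection are
    unmatched. On small instances this greedy refinement attains the optimum
    over all edge subsets (asserted against brute force in the test suite).
    """
    cfg = cfg or ScoreConfig()
    ref.check_same_grid(pred)
    ref_labels, n_ref = label_lesions(ref)
    pred_labels, n_pred = label_lesions(pred)
    ov = _Overlap(ref_labels, n_ref, pred_labels, n_pred)

    edges = list(ov.edges)
    best = ov.objective(edges)
    improved = True
    while improved and edges:
        improved = False
        best_edge = None
        for e in edges:
            trial = ov.objective([x for x in edges if x != e])
            if trial > best + 1e-12:
                best, best_edge, improved = trial, e, True
        if best_edge is not None:
            edges.remove(best_edge)

    correspondences: list[Correspondence] = []
    unmatched_ref: list[int] = []
    unmatched_pred: list[int] = []
    for ref_ids, pred_ids in _connected_groups(n_ref, n_pred, edges):
        if ref_ids and pred_ids:
            correspondences.append(Correspondence(
                tuple(i + 1 for i in ref_ids), tuple(j + 1 for j in pred_ids),
                ov.group_dice(ref_ids, pred_ids)))
        elif ref_ids:
            unmatched_ref.extend(i + 1 for i in ref_ids)
        else:
            unmatched_pred.extend(j + 1 for j in pred_ids)
    return CorrespondenceSet(correspondences, sorted(unmatched_ref),
                             sorted(unmatched_pred), n_ref, n_pred)


# ------------------------------------------------------------ detection counts

@dataclass
class DetectionCounts:
    """Lesion-wise detection counts and derived rates for one case."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    fpc: int


def detection_metrics(c: CorrespondenceSet, cfg: ScoreConfig | None = None
                      ) -> DetectionCounts:
    """Derive TP/FP/FN and recall/precision/F1/FPC from a correspondence set.

    Degenerate conventions (documented, applied consistently): with no
    positive calls precision is 1, with no reference lesions recall is 1,
    and F1 is 1 when its denominator vanishes.
    """
    cfg = cfg or ScoreConfig()
    tp = fp = fn = 0
    for corr in c.correspondences:
        if corr.dice > cfg.dice_threshold:
            tp += 1
        else:
            fp += 1
            fn += 1
    fn += len(c.unmatched_ref)
    fp += len(c.unmatched_pred)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 1.0
    return DetectionCounts(tp, fp, fn, recall, precision, f1, fpc=fp)


# ----------------------------------------------------------------- case scores

@dataclass
class CaseScores:
    """Segmentation scores of one case against a panel of raters."""

    rater_dice: list[float]
    mean_rater_dice: float                      # mean D(A, R_i)
    pairwise_dice: list[float] = field(default_factory=list)
    mean_pairwise_dice: float = np.nan          # mean D(R_i, R_j)
    eps_hat: float = np.nan
    eps_bar: float = np.nan
    phi: float = np.nan
    phi_defined: bool = False


def score_case(pred: MaskVolume, raters: list[MaskVolume],
               cfg: ScoreConfig | None = None) -> CaseScores:
    """Dice against every rater plus the uncertainty-aware score.

    The score phi needs at least two raters and nonzero inter-rater
    disagreement; otherwise it is marked undefined (``phi_defined=False``,
    logged) and the Dice summaries are still returned.
    """
    cfg = cfg or ScoreConfig()
    if not raters:
        raise ValueError("need at least one rater")
    rater_dice = [dice(pred, r) for r in raters]
    scores = CaseScores(rater_dice=rater_dice,
                        mean_rater_dice=float(np.mean(rater_dice)))
    scores.eps_hat = 1.0 - scores.mean_rater_dice
    if len(raters) >= 2:
        pairs = [dice(a, b) for a, b in itertools.combinations(raters, 2)]
        scores.pairwise_dice = pairs
        scores.mean_pairwise_dice = float(np.mean(pairs))
        scores.eps_bar = 1.0 - scores.mean_pairwise_dice
        try:
            scores.phi = uncertainty_aware_score(
                scores.mean_rater_dice, scores.mean_pairwise_dice, cfg.alpha)
            scores.phi_defined = True
        except ValueError:
            log.warning("perfect rater agreement: phi undefined for this case")
    else:
        log.warning("single rater: uncertainty-aware score unavailable")
    return scores


# ------------------------------------------------------------ paired testing

def paired_tests(comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
                 fdr: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests with Benjamini-Hochberg control.

    ``comparisons`` maps a name to a pair of equal-length per-case score
    arrays. Returns a DataFrame with the raw p-value, the BH-adjusted
    p-value, and the rejection decision at the given false discovery rate.
    All-zero differences give p = 1 by convention (logged). The exact null
    distribution is used for small samples without ties, the tie-corrected
    normal approximation otherwise (scipy's automatic policy).
    """
    names, pvals = [], []
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"comparison '{name}': unequal lengths")
        if len(a) < 6:
            log.warning("comparison '%s': fewer than 6 pairs, test has no power", name)
        if np.all(a == b):
            log.warning("comparison '%s': all differences zero, p = 1", name)
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        names.append(name)
        pvals.append(p)
    reject, p_adj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return pd.DataFrame({"comparison": names, "p_raw": pvals,
                         "p_adjusted": p_adj, "reject": reject})
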