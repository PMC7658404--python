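"""Performance metrics and downstream validation analyses.

Covers the confusion-count bookkeeping, sensitivity/specificity and their
harmonic mean, ROC/AUC on vote counts (with a stratified-bootstrap CI),
hierarchical-clustering concordance between predicted classes and
expression structure, a per-site differential-methylation screen on beta
values, and the hypergeometric overlap test for gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .preprocess import MethylationData
from .reo_screen import align_labels, bh_adjust
from .signature import f_score

__all__ = [
    "ClusterConcordance",
    "ConfusionCounts",
    "Metrics",
    "cluster_concordance",
    "confusion",
    "diff_methylation",
    "hypergeom_overlap",
    "metrics_from_confusion",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; class 1 is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    f: float


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts from predicted and true labels (1 = positive).

    Both inputs are Series indexed by sample (or aligned arrays); the
    sample sets must match exactly.
    """
    pred = pd.Series(pred)
    truth = pd.Series(truth)
    if isinstance(pred.index, pd.RangeIndex) and isinstance(truth.index, pd.RangeIndex):
        if len(pred) != len(truth):
            raise ValueError("prediction and truth lengths differ")
    else:
        if set(pred.index) != set(truth.index):
            raise ValueError("prediction and truth sample sets differ")
        truth = truth.reindex(pred.index)
    p = pred.to_numpy() == 1
    t = truth.to_numpy() == 1
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and their harmonic mean from counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be represented in the truth")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return Metrics(sensitivity=sens, specificity=spec, f=f_score(sens, spec))


def _auc_rank(scores: np.ndarray, pos: np.ndarray) -> float:
    # midrank formulation: P(s_pos > s_neg) + 0.5 P(tie)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = stats.rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(
    scores,
    truth,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC of a score (vote counts) against binary truth, with 95% CI.

    Ties receive the standard 1/2 credit, matching the ROC curve built
    from every achievable threshold. The CI comes from ``n_boot``
    stratified bootstrap resamples (classes resampled separately) with a
    fixed seed.
    """
    s = np.asarray(scores, dtype=float)
    t = pd.Series(truth).to_numpy()
    pos = t == 1 if t.dtype != bool else t
    if not pos.any() or pos.all():
        raise ValueError("both classes required for ROC analysis")
    auc = _auc_rank(s, pos)
    rng = np.random.default_rng(seed)
    ip, ineg = np.flatnonzero(pos), np.flatnonzero(~pos)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(ip, size=ip.size, replace=True)
        rn = rng.choice(ineg, size=ineg.size, replace=True)
        sb = np.concatenate([s[rp], s[rn]])
        pb = np.zeros(sb.size, dtype=bool)
        pb[: rp.size] = True
        boots[b] = _auc_rank(sb, pb)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


@dataclass
class ClusterConcordance:
    assignment: pd.Series  # sample -> cluster-mapped class (1/2)
    agreement: float  # fraction of disputed samples matching prediction
    ambiguous: bool  # True when a cluster held no reference samples


def cluster_concordance(
    expr: pd.DataFrame,
    predicted: pd.Series,
    ref_pos,
    ref_neg,
    top_n: int = 100,
) -> ClusterConcordance:
    """Check predicted classes against unsupervised expression structure.

    Picks the ``top_n`` genes most differential between the reference
    (signature-confirmed) positive and negative samples, clusters *all*
    samples by complete-linkage on Euclidean distances, cuts the dendrogram
    into two clusters, maps each cluster to a class by majority of its
    reference samples, and reports the fraction of non-reference (disputed)
    samples whose cluster agrees with their predicted class.
    """
    ref_pos, ref_neg = set(ref_pos), set(ref_neg)
    if ref_pos & ref_neg:
        raise ValueError("reference sets must be disjoint")
    if not ref_pos or not ref_neg:
        raise ValueError("both reference sets must be non-empty")
    if top_n > expr.shape[0]:
        raise ValueError("top_n exceeds the gene count")

    ref_labels = pd.Series(
        {**{s: 1 for s in ref_pos}, **{s: 2 for s in ref_neg}}
    )
    g1, g2 = align_labels(expr, ref_labels)
    values = expr.to_numpy(dtype=float)
    p = stats.ttest_ind(values[:, g1], values[:, g2], axis=1, equal_var=False).pvalue
    p = np.nan_to_num(p, nan=1.0)
    bh_adjust(p)  # adjusted q available; ranking for selection uses p
    top_idx = np.lexsort((expr.index.astype(str), p))[:top_n]

    sub = values[top_idx]  # top_n x samples
    z = linkage(pdist(sub.T, metric="euclidean"), method="complete")
    clusters = fcluster(z, t=2, criterion="maxclust")

    samples = expr.columns
    mapping: dict[int, int] = {}
    ambiguous = False
    for cl in (1, 2):
        members = set(samples[clusters == cl])
        n_pos_ref = len(members & ref_pos)
        n_neg_ref = len(members & ref_neg)
        if n_pos_ref == 0 and n_neg_ref == 0:
            ambiguous = True
        elif n_pos_ref == n_neg_ref:
            ambiguous = True
        else:
            mapping[cl] = 1 if n_pos_ref > n_neg_ref else 2
    assignment = pd.Series(
        [mapping.get(cl, 0) for cl in clusters], index=samples, name="class"
    )

    disputed = [s for s in samples if s not in ref_pos and s not in ref_neg]
    if disputed and not ambiguous:
        pred = pd.Series(predicted).reindex(disputed)
        agree = float((assignment.loc[disputed].to_numpy() == pred.to_numpy()).mean())
    else:
        agree = float("nan")
    return ClusterConcordance(assignment=assignment, agreement=agree, ambiguous=ambiguous)


def diff_methylation(
    beta,
    labels: pd.Series,
    p_threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Per-site differential screen on methylation beta values.

    Welch's t on beta per site; sites with unadjusted P < ``p_threshold``
    split into hyper (group-1 mean higher) and hypo (group-1 mean lower)
    lists. The unadjusted threshold mirrors the usual exploratory screen;
    pass BH-adjusted cutoffs upstream if stricter control is wanted.
    """
    frame = beta.beta if isinstance(beta, MethylationData) else beta
    g1, g2 = align_labels(frame, labels)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    values = frame.to_numpy(dtype=float)
    x1, x2 = values[:, g1], values[:, g2]
    p = stats.ttest_ind(x1, x2, axis=1, equal_var=False).pvalue
    p = np.nan_to_num(p, nan=1.0)
    delta = x1.mean(axis=1) - x2.mean(axis=1)
    sig = p < p_threshold
    sites = frame.index.astype(str)
    hyper = [s for s, ok, d in zip(sites, sig, delta) if ok and d > 0]
    hypo = [s for s, ok, d in zip(sites, sig, delta) if ok and d < 0]
    return hyper, hypo


def hypergeom_overlap(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric P that |a ∩ b| is at least as large as seen.

    With universe size N, drawing |a| items, |b| of which are marked,
    returns P(X >= |a ∩ b|).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(a & b)
    return float(stats.hypergeom.sf(overlap - 1, len(u), len(b), len(a)))
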