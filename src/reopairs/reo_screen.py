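"""Differential-expression gating and phenotype-associated gene-pair screening.

The screen works on relative expression orderings (REOs): for a gene pair
(i, j) and phenotype group c, p_ij(c) = P(E_i > E_j | c) is the within-group
frequency of the ordering, estimated by counting samples. A pair is
phenotype-associated when the group-wise 2x2 ordering table is significant
by Fisher's exact test after Benjamini-Hochberg adjustment across all tested
pairs. Each retained pair is oriented so the pattern E_up > E_down is the
one more frequent in group 1 (the positive class), making the frequency
difference fd = p1 - p2 positive.

Because only within-sample orderings enter, every statistic here is
invariant to any strictly increasing transform applied per sample — the
property that makes REO signatures robust to batch effects and scale
differences between platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrientedGenePair",
    "align_labels",
    "bh_adjust",
    "de_screen",
    "fisher_pair_test",
    "frame_to_pairs",
    "pairs_to_frame",
    "reo_frequencies",
    "screen_pairs",
]

PAIR_COLUMNS = ["g_up", "g_down", "p1", "p2", "fd", "p_value", "fdr"]


@dataclass(frozen=True)
class OrientedGenePair:
    """An ordered gene pair whose pattern E_up > E_down favors group 1."""

    g_up: str
    g_down: str
    p1: float
    p2: float
    fd: float
    p_value: float = np.nan
    fdr: float = np.nan


def pairs_to_frame(pairs) -> pd.DataFrame:
    rows = [
        (p.g_up, p.g_down, p.p1, p.p2, p.fd, p.p_value, p.fdr) for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[OrientedGenePair]:
    return [
        OrientedGenePair(
            str(r.g_up),
            str(r.g_down),
            float(r.p1),
            float(r.p2),
            float(r.fd),
            float(r.p_value),
            float(r.fdr),
        )
        for r in frame.itertuples(index=False)
    ]


def align_labels(expr: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over expr columns for groups 1 and 2.

    Every labeled sample must be a column of expr; both groups must be
    non-empty. Unlabeled columns are ignored.
    """
    missing = labels.index.difference(expr.columns)
    if len(missing) > 0:
        raise ValueError(f"labeled samples absent from matrix: {list(missing)[:10]}")
    lab = labels.reindex(expr.columns)
    g1 = (lab == 1).to_numpy()
    g2 = (lab == 2).to_numpy()
    if not g1.any() or not g2.any():
        raise ValueError("both phenotype groups must be non-empty")
    return g1, g2


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.01,
    method: str = "welch_t",
    log2: bool = False,
) -> pd.DataFrame:
    """Two-group differential-expression screen with BH-FDR.

    A moderated/standard two-sample t-test gates the pair space: only pairs
    anchored on a differential gene are screened downstream. ``welch_t`` is
    Welch's unequal-variance t; ``moderated_t`` shrinks per-gene pooled
    variances toward their mean with a fixed prior weight d0 = 4 and adds d0
    to the residual degrees of freedom. ``log2`` applies log2 before testing
    (for linear-scale intensities); never autodetected.

    Returns the genes with FDR < ``alpha`` as a DataFrame (index gene_id,
    columns ``p`` and ``fdr``) sorted by p ascending, ties by gene ID.
    """
    g1, g2 = align_labels(expr, labels)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    values = expr.to_numpy(dtype=float)
    if log2:
        if (values <= 0).any():
            raise ValueError("log2 requested but matrix has values <= 0")
        values = np.log2(values)
    x1, x2 = values[:, g1], values[:, g2]
    if method == "welch_t":
        p = stats.ttest_ind(x1, x2, axis=1, equal_var=False).pvalue
    elif method == "moderated_t":
        p = _moderated_t_p(x1, x2)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.nan_to_num(p, nan=1.0)  # zero-variance genes are non-findings
    fdr = bh_adjust(p)
    table = pd.DataFrame({"p": p, "fdr": fdr}, index=expr.index)
    selected = table[table["fdr"] < alpha]
    order = np.lexsort((selected.index.astype(str), selected["p"].to_numpy()))
    return selected.iloc[order]


def _moderated_t_p(x1: np.ndarray, x2: np.ndarray, d0: float = 4.0) -> np.ndarray:
    # pooled per-gene variance shrunk toward the across-gene mean variance
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    s2 = ((x1.var(axis=1, ddof=1) * (n1 - 1)) + (x2.var(axis=1, ddof=1) * (n2 - 1))) / df
    s2_prior = s2.mean()
    s2_mod = (d0 * s2_prior + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(np.abs(t), df + d0)


def reo_frequencies(
    expr: pd.DataFrame, i: str, j: str, labels: pd.Series
) -> tuple[float, float, np.ndarray]:
    """Within-group ordering frequencies for a gene pair.

    Returns ``(p1, p2, table)`` where p_c is the fraction of group-c samples
    with E_i > E_j (ties count against the pattern) and table is the 2x2
    count matrix ``[[a, n1-a], [b, n2-b]]`` with a, b the group-wise counts
    of E_i > E_j.
    """
    for g in (i, j):
        if g not in expr.index:
            raise KeyError(f"gene {g!r} absent from matrix")
    g1, g2 = align_labels(expr, labels)
    gt = expr.loc[i].to_numpy() > expr.loc[j].to_numpy()
    n1, n2 = int(g1.sum()), int(g2.sum())
    a, b = int(gt[g1].sum()), int(gt[g2].sum())
    table = np.array([[a, n1 - a], [b, n2 - b]])
    return a / n1, b / n2, table


@lru_cache(maxsize=200_000)
def _fisher_ab(a: int, n1: int, b: int, n2: int) -> float:
    return float(
        stats.fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")[1]
    )


def fisher_pair_test(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 ordering-count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t[0].sum() == 0 or t[1].sum() == 0:
        raise ValueError("both row sums must be positive")
    return _fisher_ab(int(t[0, 0]), int(t[0].sum()), int(t[1, 0]), int(t[1].sum()))


def screen_pairs(
    expr: pd.DataFrame,
    labels: pd.Series,
    de_genes,
    alpha: float = 0.01,
    pair_space: str = "de_by_all",
) -> pd.DataFrame:
    """Screen candidate gene pairs for phenotype-associated orderings.

    Candidate pairs are the unordered pairs with at least one member in
    ``de_genes`` (``de_by_all``, the default) or both members differential
    (``de_by_de``). For every candidate the group-wise ordering counts are
    tested with Fisher's exact test; BH adjustment runs across *all* tested
    pairs, and pairs with FDR < ``alpha`` are retained, oriented so
    fd = p1 - p2 > 0, and sorted by fd descending, then p ascending, then
    (g_up, g_down) lexicographic.
    """
    de_list = sorted(str(g) for g in set(de_genes))
    if not de_list:
        raise ValueError(
            "no differential genes supplied; loosen the DE FDR threshold"
        )
    missing = set(de_list) - set(expr.index.astype(str))
    if missing:
        raise KeyError(f"DE genes absent from matrix: {sorted(missing)[:10]}")
    if pair_space not in ("de_by_all", "de_by_de"):
        raise ValueError(f"unknown pair_space {pair_space!r}")

    # canonical gene order so results are independent of input row order
    gene_order = np.array(sorted(expr.index.astype(str)))
    values = expr.loc[gene_order].to_numpy(dtype=float)
    g1, g2 = align_labels(expr.loc[gene_order], labels)
    n1, n2 = int(g1.sum()), int(g2.sum())
    pos_of = {g: k for k, g in enumerate(gene_order)}
    de_pos = np.array([pos_of[g] for g in de_list])
    de_mask = np.zeros(len(gene_order), dtype=bool)
    de_mask[de_pos] = True

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    a_all: list[np.ndarray] = []
    b_all: list[np.ndarray] = []
    seen_de = np.zeros(len(gene_order), dtype=bool)
    for d in de_pos:
        if pair_space == "de_by_all":
            partner = np.ones(len(gene_order), dtype=bool)
        else:
            partner = de_mask.copy()
        partner[d] = False
        partner &= ~seen_de  # unordered pairs: drop partners already anchored
        seen_de[d] = True
        idx = np.flatnonzero(partner)
        if idx.size == 0:
            continue
        gt = values[d][None, :] > values[idx]  # (#partners, #samples)
        a = gt[:, g1].sum(axis=1)
        b = gt[:, g2].sum(axis=1)
        rows_i.append(np.full(idx.size, d))
        rows_j.append(idx)
        a_all.append(a)
        b_all.append(b)

    if not rows_i:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    ii = np.concatenate(rows_i)
    jj = np.concatenate(rows_j)
    a = np.concatenate(a_all)
    b = np.concatenate(b_all)

    # Fisher p depends only on (a, b) given the group sizes: memoize
    combo = a * (n2 + 1) + b
    uniq, inverse = np.unique(combo, return_inverse=True)
    p_uniq = np.array(
        [_fisher_ab(int(u // (n2 + 1)), n1, int(u % (n2 + 1)), n2) for u in uniq]
    )
    p = p_uniq[inverse]
    fdr = bh_adjust(p)

    keep = fdr < alpha
    if not keep.any():
        return pd.DataFrame(columns=PAIR_COLUMNS)
    ii, jj, a, b, p, fdr = ii[keep], jj[keep], a[keep], b[keep], p[keep], fdr[keep]
    p1 = a / n1
    p2 = b / n2
    flip = p1 < p2  # orient toward the pattern favored in group 1
    g_up = np.where(flip, gene_order[jj], gene_order[ii])
    g_down = np.where(flip, gene_order[ii], gene_order[jj])
    p1o = np.where(flip, 1.0 - p1, p1)  # ties are measure-zero in the data
    p2o = np.where(flip, 1.0 - p2, p2)
    # exact tie counts need recounting only when ties exist; recount lazily
    if flip.any():
        tie = _has_ties(values, ii[flip], jj[flip])
        if tie.any():
            sel = np.flatnonzero(flip)[tie]
            for s in sel:
                lt1 = (values[jj[s]][g1] > values[ii[s]][g1]).sum()
                lt2 = (values[jj[s]][g2] > values[ii[s]][g2]).sum()
                p1o[s] = lt1 / n1
                p2o[s] = lt2 / n2
    fd = p1o - p2o
    out = pd.DataFrame(
        {
            "g_up": g_up,
            "g_down": g_down,
            "p1": p1o,
            "p2": p2o,
            "fd": fd,
            "p_value": p,
            "fdr": fdr,
        }
    )
    out = out[out["fd"] > 0]
    order = np.lexsort(
        (
            out["g_down"].to_numpy(),
            out["g_up"].to_numpy(),
            out["p_value"].to_numpy(),
            -out["fd"].to_numpy(),
        )
    )
    return out.iloc[order].reset_index(drop=True)


def _has_ties(values: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    return np.array(
        [(values[i] == values[j]).any() for i, j in zip(ii, jj)], dtype=bool
    )
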