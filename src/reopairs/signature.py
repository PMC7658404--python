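"""Panel construction, vote-threshold optimization and classification.

From the screened candidate pairs, a signature is built in three steps:

1. an FD-cutoff scan — panels of pairs with frequency difference at least
   each cutoff on a fixed 0.01-spaced grid;
2. redundancy removal within each panel — a greedy sweep in (fd desc,
   p asc, lexicographic) order that keeps a pair only if neither of its
   genes already appears in a kept pair;
3. vote-threshold optimization — for every k from 1 to the panel size, the
   rule "positive iff at least k pairs show their positive-class ordering"
   is evaluated on the training labels and the k maximizing
   F = 2*sens*spec/(sens+spec) is kept.

The panel/k combination with the largest training F-score becomes the
signature. Classification needs only within-sample orderings, so it is
invariant to any per-sample strictly increasing transform of expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .reo_screen import (
    OrientedGenePair,
    align_labels,
    de_screen,
    frame_to_pairs,
    pairs_to_frame,
    screen_pairs,
)

__all__ = [
    "PanelScanRecord",
    "Signature",
    "adapt_to_platform",
    "classify",
    "f_score",
    "fd_cutoff_scan",
    "optimize_vote_rule",
    "redundancy_removal",
    "train_signature",
    "vote_count",
    "vote_counts",
]

SIGNATURE_FORMAT_VERSION = 1


@dataclass
class Signature:
    """A trained gene-pair panel with its majority-vote threshold.

    A sample is called positive when at least ``k`` of the ``pairs`` show
    E_up > E_down in that sample.
    """

    pairs: list[OrientedGenePair]
    k: int
    fd_cutoff: float
    training_f_score: float
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.k <= len(self.pairs)):
            raise ValueError(f"k={self.k} outside 1..{len(self.pairs)}")
        genes = self.genes()
        if len(genes) != 2 * len(self.pairs):
            raise ValueError("a gene appears in more than one signature pair")
        if any(p.fd < self.fd_cutoff - 1e-12 for p in self.pairs):
            raise ValueError("pair below the signature's FD cutoff")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update((p.g_up, p.g_down))
        return out

    def to_dict(self) -> dict:
        return {
            "version": SIGNATURE_FORMAT_VERSION,
            "pairs": [asdict(p) for p in self.pairs],
            "k": self.k,
            "fd_cutoff": self.fd_cutoff,
            "training": {"f_score": self.training_f_score, **self.training},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        if d.get("version") != SIGNATURE_FORMAT_VERSION:
            raise ValueError(f"unsupported signature version {d.get('version')!r}")
        training = dict(d.get("training", {}))
        f = training.pop("f_score", np.nan)
        pairs = [OrientedGenePair(**p) for p in d["pairs"]]
        return cls(
            pairs=pairs,
            k=int(d["k"]),
            fd_cutoff=float(d["fd_cutoff"]),
            training_f_score=float(f),
            training=training,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Signature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PanelScanRecord:
    fd_cutoff: float
    panel_size: int
    best_k: int
    best_f_score: float


def _canonical_sort(frame: pd.DataFrame) -> pd.DataFrame:
    order = np.lexsort(
        (
            frame["g_down"].to_numpy(),
            frame["g_up"].to_numpy(),
            frame["p_value"].to_numpy(),
            -frame["fd"].to_numpy(),
        )
    )
    return frame.iloc[order]


def redundancy_removal(pairs: pd.DataFrame, presorted: bool = False) -> pd.DataFrame:
    """Keep, per gene, only its largest-FD pair.

    Greedy sweep in (fd desc, p asc, lexicographic) order: a pair survives
    iff neither gene occurs in an already-kept pair, so no gene appears
    twice in the output. Output preserves sweep order. ``presorted`` skips
    the sort when the input is already in sweep order.
    """
    if len(pairs) == 0:
        return pairs.copy()
    swept = pairs if presorted else _canonical_sort(pairs)
    used: set[str] = set()
    keep_rows: list[int] = []
    for pos, (up, down) in enumerate(zip(swept["g_up"], swept["g_down"])):
        if up not in used and down not in used:
            keep_rows.append(pos)
            used.add(up)
            used.add(down)
    return swept.iloc[keep_rows].reset_index(drop=True)


def vote_counts(expr: pd.DataFrame, pairs: pd.DataFrame | list) -> pd.Series:
    """Per-sample count of pairs showing their positive-class ordering."""
    frame = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    missing = (set(frame["g_up"]) | set(frame["g_down"])) - set(expr.index)
    if missing:
        raise KeyError(
            f"signature genes absent from matrix: {sorted(missing)[:10]}; "
            "adapt the signature to this platform first"
        )
    up = expr.loc[frame["g_up"].to_numpy()].to_numpy(dtype=float)
    down = expr.loc[frame["g_down"].to_numpy()].to_numpy(dtype=float)
    votes = (up > down).sum(axis=0)
    return pd.Series(votes, index=expr.columns, name="votes")


def vote_count(sample_expr: pd.Series, pairs) -> int:
    """Votes for a single sample; ties (E_up == E_down) do not vote."""
    frame = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    return int(vote_counts(sample_expr.to_frame(), frame).iloc[0])


def f_score(sens: float, spec: float) -> float:
    """Harmonic mean of sensitivity and specificity (this family's F-score)."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if sens + spec == 0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


def optimize_vote_rule(
    votes, labels, m: int
) -> tuple[int, float, float, float]:
    """Exhaustive scan of the vote threshold k on training labels.

    Evaluates "predict positive iff votes >= k" for every k in 1..m and
    returns ``(k, f, sens, spec)`` at the F-score maximum; ties break
    toward larger k (the stricter rule).
    """
    v = np.asarray(votes, dtype=int)
    y = np.asarray(labels)
    pos = y == 1 if y.dtype != bool else y
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to optimize the vote rule")
    if (v < 0).any() or (v > m).any():
        raise ValueError(f"votes must lie in 0..{m}")
    best = None
    for k in range(1, m + 1):
        pred = v >= k
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        f = f_score(sens, spec)
        if best is None or f >= best[1]:  # >= : ties go to larger k
            best = (k, f, sens, spec)
    return best


def fd_cutoff_scan(
    candidates: pd.DataFrame,
    expr: pd.DataFrame,
    labels: pd.Series,
    spacing: float = 0.01,
    removal_stage: str = "per_panel",
    training_meta: dict | None = None,
) -> tuple[Signature, list[PanelScanRecord]]:
    """Scan FD cutoffs, optimize each panel's vote rule, keep the best.

    The cutoff grid is the multiples of ``spacing`` between the smallest
    and largest candidate FD (anchored at multiples of spacing, so cutoffs
    are platform-independent). For each cutoff the panel of pairs with
    fd >= cutoff undergoes redundancy removal (``removal_stage="global"``
    removes redundancy once up front instead) and an exhaustive vote-rule
    scan. Returns the signature from the highest-F-score record; ties break
    toward larger cutoff (smaller panel), then larger k.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate pairs to scan")
    if removal_stage not in ("per_panel", "global"):
        raise ValueError(f"unknown removal_stage {removal_stage!r}")
    pool = _canonical_sort(candidates).reset_index(drop=True)
    if removal_stage == "global":
        pool = redundancy_removal(pool, presorted=True)
    fd = pool["fd"].to_numpy()
    hi = int(np.floor(fd.max() / spacing + 1e-9))
    lo = int(np.ceil(fd.min() / spacing - 1e-9))
    if hi >= lo:
        cutoffs = [m * spacing for m in range(hi, lo - 1, -1)]
    else:  # all fd equal and off-grid: degenerate single cutoff
        cutoffs = [float(fd.min())]

    g1, g2 = align_labels(expr, labels)
    y = np.where(g1, 1, 2)

    records: list[PanelScanRecord] = []
    best = None  # (f, cutoff, k, panel_frame, sens, spec)
    for cutoff in cutoffs:
        panel = pool[fd >= cutoff - 1e-12]
        if removal_stage == "per_panel":
            panel = redundancy_removal(panel, presorted=True)
        if len(panel) == 0:
            continue
        votes = vote_counts(expr, panel).to_numpy()
        k, f, sens, spec = optimize_vote_rule(votes, y, len(panel))
        records.append(PanelScanRecord(cutoff, len(panel), k, f))
        # cutoffs are scanned descending, so "first strict max" breaks ties
        # toward the larger cutoff; optimize_vote_rule already prefers larger k
        if best is None or f > best[0] + 1e-15:
            best = (f, cutoff, k, panel, sens, spec)
    f, cutoff, k, panel, sens, spec = best
    meta = dict(training_meta or {})
    meta.update(
        {
            "n_pos": int(g1.sum()),
            "n_neg": int(g2.sum()),
            "sensitivity": sens,
            "specificity": spec,
        }
    )
    sig = Signature(
        pairs=frame_to_pairs(panel),
        k=k,
        fd_cutoff=cutoff,
        training_f_score=f,
        training=meta,
    )
    return sig, records


def classify(expr: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """Apply a signature's vote rule to every sample.

    Returns a DataFrame indexed by sample with columns ``votes`` and
    ``label`` (1 = positive class, 2 = negative), where a sample is
    positive iff at least ``sig.k`` pairs vote for it.
    """
    votes = vote_counts(expr, pairs_to_frame(sig.pairs))
    label = np.where(votes.to_numpy() >= sig.k, 1, 2)
    return pd.DataFrame({"votes": votes, "label": label}, index=expr.columns)


def adapt_to_platform(
    sig: Signature,
    available_genes,
    training_expr: pd.DataFrame,
    training_labels: pd.Series,
) -> Signature:
    """Restrict a signature to the pairs measurable on a platform.

    Pairs with either gene missing from ``available_genes`` are dropped and
    the vote threshold is re-optimized on the original training cohort
    restricted to the surviving pairs (the threshold is a property of the
    panel, so a smaller panel needs its own exhaustive k scan).
    """
    avail = set(map(str, available_genes))
    surviving = [p for p in sig.pairs if p.g_up in avail and p.g_down in avail]
    if not surviving:
        raise ValueError("no signature pair fully measurable on this platform")
    if len(surviving) == len(sig.pairs):
        return sig
    frame = pairs_to_frame(surviving)
    votes = vote_counts(training_expr, frame).to_numpy()
    g1, _ = align_labels(training_expr, training_labels)
    y = np.where(g1, 1, 2)
    k, f, sens, spec = optimize_vote_rule(votes, y, len(surviving))
    meta = dict(sig.training)
    meta.update(
        {
            "adapted_from_panel_size": len(sig.pairs),
            "sensitivity": sens,
            "specificity": spec,
        }
    )
    return Signature(
        pairs=surviving,
        k=k,
        fd_cutoff=sig.fd_cutoff,
        training_f_score=f,
        training=meta,
    )


def train_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    de_fdr: float = 0.01,
    pair_fdr: float = 0.01,
    spacing: float = 0.01,
    de_method: str = "welch_t",
    log2: bool = False,
    pair_space: str = "de_by_all",
    removal_stage: str = "per_panel",
    cohort: str = "training",
) -> tuple[Signature, list[PanelScanRecord], dict]:
    """End-to-end training: DE gate -> pair screen -> FD scan -> signature.

    Returns the signature, the per-cutoff scan records, and a stage-count
    dict (DE genes, candidate pairs, panels scanned).
    """
    de = de_screen(expr, labels, alpha=de_fdr, method=de_method, log2=log2)
    candidates = screen_pairs(
        expr, labels, de.index, alpha=pair_fdr, pair_space=pair_space
    )
    if len(candidates) == 0:
        raise ValueError("no phenotype-associated pairs at this FDR threshold")
    sig, records = fd_cutoff_scan(
        candidates,
        expr,
        labels,
        spacing=spacing,
        removal_stage=removal_stage,
        training_meta={"cohort": cohort},
    )
    info = {
        "n_de_genes": int(len(de)),
        "n_candidate_pairs": int(len(candidates)),
        "n_panels_scanned": len(records),
        "chosen_fd_cutoff": sig.fd_cutoff,
        "panel_size": len(sig.pairs),
        "k": sig.k,
        "training_f_score": sig.training_f_score,
    }
    return sig, records, info
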