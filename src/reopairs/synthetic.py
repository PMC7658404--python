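"""Synthetic two-group cohorts with planted gene-pair ordering structure.

The generator realizes directly the statistical abstraction the screen
estimates: for each planted pair, the ordering E_up > E_down holds with
probability ``pi_pos`` in positive samples and ``pi_neg`` in negative
samples. Per sample, a Bernoulli draw decides the intended winner, which
receives a +delta mean offset (the loser -delta, delta = 2 * noise_sd)
before Gaussian noise is added; in the rare samples where the noise still
contradicts the draw, the pair's two values are swapped, so the drawn
ordering is realized exactly and the planted frequencies are binomial in
the nominal probabilities. Unplanted genes carry no group signal.
Baselines live on a log-like scale (Gaussian around 8, resembling log2
microarray intensities).

Probe-level replication, per-sample monotone distortions, platform gene
dropout and methylation intensities are provided so every pipeline stage
has a ground-truthed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MethylationData
from .reo_screen import OrientedGenePair

__all__ = [
    "GroundTruth",
    "SyntheticConfig",
    "corrupt_monotone",
    "generate_cohort",
    "generate_methylation",
    "to_probe_level",
]

BASELINE_MEAN = 8.0  # center of the log-like baseline distribution


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the reference conditions used throughout the test
    suite: 2000 genes, 30 planted pairs with ordering probabilities
    0.95/0.05, and a 60+120 positive/negative cohort.
    """

    n_genes: int = 2000
    n_pos: int = 60
    n_neg: int = 120
    n_planted_pairs: int = 30
    pi_pos: float = 0.95
    pi_neg: float = 0.05
    base_log_mean_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    probe_replicates: int = 1
    dropout_genes: int = 0
    overlap_pairs: bool = False
    n_sites: int = 1000
    n_dm_sites: int = 100
    beta_shift: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.pi_neg <= self.pi_pos <= 1):
            raise ValueError("need 0 <= pi_neg <= pi_pos <= 1")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError("planted pairs need 2*n_planted_pairs <= n_genes")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both groups must be non-empty")


@dataclass
class GroundTruth:
    """What was planted: oriented pairs, DM sites, dropped-out genes."""

    planted_pairs: list[OrientedGenePair] = field(default_factory=list)
    dm_sites: list[str] = field(default_factory=list)
    dropout_genes: list[str] = field(default_factory=list)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.g_up, p.g_down) for p in self.planted_pairs}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_pos: int, n_neg: int) -> tuple[list[str], pd.Series]:
    ids = [f"S{i:04d}" for i in range(1, n_pos + n_neg + 1)]
    labels = pd.Series([1] * n_pos + [2] * n_neg, index=ids, name="group")
    return ids, labels


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw a cohort with planted pair orderings; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    samples, labels = _sample_ids(cfg.n_pos, cfg.n_neg)
    n = cfg.n_pos + cfg.n_neg
    is_pos = (labels == 1).to_numpy()

    mu = BASELINE_MEAN + rng.normal(0.0, cfg.base_log_mean_sd, size=cfg.n_genes)

    if cfg.overlap_pairs:
        # chained pairs sharing genes, to exercise redundancy removal
        pair_idx = [(t, t + 1) for t in range(cfg.n_planted_pairs)]
    else:
        pair_idx = [(2 * t, 2 * t + 1) for t in range(cfg.n_planted_pairs)]
    for up, down in pair_idx:
        shared = BASELINE_MEAN + rng.normal(0.0, cfg.base_log_mean_sd)
        mu[up] = shared
        mu[down] = shared

    values = np.tile(mu[:, None], (1, n))
    delta = 2.0 * cfg.noise_sd
    planted: list[OrientedGenePair] = []
    wins: list[np.ndarray] = []
    for up, down in pair_idx:
        pi = np.where(is_pos, cfg.pi_pos, cfg.pi_neg)
        win_up = rng.random(n) < pi
        sign = np.where(win_up, 1.0, -1.0)
        values[up] += sign * delta
        values[down] -= sign * delta
        wins.append(win_up)
        planted.append(
            OrientedGenePair(
                g_up=genes[up],
                g_down=genes[down],
                p1=cfg.pi_pos,
                p2=cfg.pi_neg,
                fd=cfg.pi_pos - cfg.pi_neg,
            )
        )
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    # the Bernoulli draw IS the ground truth: where noise contradicted the
    # intended ordering (~0.2% of draws at delta = 2*noise_sd), swap the
    # pair's two values in that sample — marginals are preserved and the
    # planted ordering frequencies become exactly binomial in pi
    for (up, down), win_up in zip(pair_idx, wins):
        actual = values[up] > values[down]
        mism = actual != win_up
        if mism.any():
            values[up][mism], values[down][mism] = (
                values[down][mism].copy(),
                values[up][mism].copy(),
            )

    dropout: list[str] = []
    if cfg.dropout_genes:
        # prefer planted genes so platform adaptation is actually exercised
        planted_genes = [genes[i] for pr in pair_idx for i in pr]
        pool = planted_genes + [g for g in genes if g not in set(planted_genes)]
        dropout = pool[: cfg.dropout_genes]

    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = GroundTruth(planted_pairs=planted, dropout_genes=dropout)
    return expr, labels, truth


def to_probe_level(
    expr: pd.DataFrame,
    replicates: int = 3,
    probe_noise_sd: float = 0.1,
    n_unmapped: int = 0,
    n_multimapped: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix to probes plus decoy probes.

    Each gene becomes ``replicates`` probes: gene value + a probe-specific
    offset (zero-mean within the gene) + per-cell noise. Decoy unmapped and
    multimapped probes carry random values and must vanish on collapsing.
    Returns the probe matrix and a probe map in the loader's format
    (indexed by probe_id, columns ``gene_id`` and ``multimapped``).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_genes, n_samples = expr.shape
    offsets = rng.normal(0.0, probe_noise_sd, size=(n_genes, replicates))
    offsets -= offsets.mean(axis=1, keepdims=True)  # collapse is unbiased

    rows = []
    probe_ids = []
    gene_col = []
    multi_col = []
    values = expr.to_numpy(dtype=float)
    for gi, gene in enumerate(expr.index):
        for r in range(replicates):
            probe_ids.append(f"{gene}_probe{r + 1}")
            gene_col.append(str(gene))
            multi_col.append(False)
            rows.append(
                values[gi]
                + offsets[gi, r]
                + rng.normal(0.0, probe_noise_sd, size=n_samples)
            )
    for i in range(n_unmapped):
        probe_ids.append(f"UNMAPPED{i + 1}")
        gene_col.append("")
        multi_col.append(False)
        rows.append(rng.normal(BASELINE_MEAN, 1.0, size=n_samples))
    for i in range(n_multimapped):
        probe_ids.append(f"MULTI{i + 1}")
        gene_col.append("")
        multi_col.append(True)
        rows.append(rng.normal(BASELINE_MEAN, 1.0, size=n_samples))

    probe_matrix = pd.DataFrame(
        np.vstack(rows), index=probe_ids, columns=expr.columns
    )
    probe_map = pd.DataFrame(
        {"gene_id": gene_col, "multimapped": multi_col}, index=pd.Index(probe_ids)
    )
    return probe_matrix, probe_map


def corrupt_monotone(
    expr: pd.DataFrame, family: str = "affine_pos", seed: int = 0
) -> pd.DataFrame:
    """Distort each sample with an independent strictly increasing transform.

    Families: ``affine_pos`` (per-sample a*x+b with a > 0), ``exp``
    (elementwise exponential), ``rank`` (per-sample midranks). Within-sample
    orderings — and hence the whole REO pipeline — are unchanged.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float).copy()
    n_samples = values.shape[1]
    if family == "affine_pos":
        a = rng.uniform(0.5, 2.0, size=n_samples)
        b = rng.uniform(-3.0, 3.0, size=n_samples)
        values = values * a[None, :] + b[None, :]
    elif family == "exp":
        values = np.exp(values - values.max(axis=0, keepdims=True) + 10.0)
    elif family == "rank":
        values = np.column_stack(
            [rankdata(values[:, s]) for s in range(n_samples)]
        )
    else:
        raise ValueError(f"unknown transform family {family!r}")
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)


def generate_methylation(
    cfg: SyntheticConfig, labels: pd.Series
) -> tuple[MethylationData, GroundTruth]:
    """Draw M/U intensity matrices whose betas carry planted DM sites.

    Background site betas sit in a bimodal mixture near 0.1 and 0.9;
    ``n_dm_sites`` sites get ``beta_shift`` added in group 1. Intensities
    are back-solved from the target beta and a lognormal total intensity T:
    M = beta * (T + 100), U = T - M, so M/(U+M+100) reproduces the target
    beta exactly.
    """
    if not (0 < cfg.beta_shift < 1):
        raise ValueError("beta_shift must lie in (0, 1)")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    n = len(labels)
    is_pos = (labels == 1).to_numpy()
    width = max(4, len(str(cfg.n_sites)))
    sites = [f"cg{i:0{width}d}" for i in range(1, cfg.n_sites + 1)]
    dm = sites[: cfg.n_dm_sites]

    low_mode = rng.random(cfg.n_sites) < 0.5
    base = np.where(low_mode, 0.1, 0.85) + rng.normal(0.0, 0.03, size=cfg.n_sites)
    base[: cfg.n_dm_sites] = rng.uniform(0.10, 0.30, size=cfg.n_dm_sites)

    beta = np.tile(base[:, None], (1, n))
    beta[: cfg.n_dm_sites, is_pos] += cfg.beta_shift
    beta += rng.normal(0.0, 0.02, size=beta.shape)
    beta = np.clip(beta, 0.001, 0.94)

    total = rng.lognormal(np.log(2000.0), 0.3, size=beta.shape)
    total = np.maximum(total, 100.0 * beta / (1 - beta) + 10.0)  # keep U >= 0
    M = beta * (total + 100.0)
    U = total - M

    chrom = pd.Series(
        [f"chr{(i % 22) + 1}" for i in range(cfg.n_sites)], index=sites
    )
    data = MethylationData(
        M=pd.DataFrame(M, index=sites, columns=labels.index),
        U=pd.DataFrame(U, index=sites, columns=labels.index),
        chromosome=chrom,
    )
    return data, GroundTruth(dm_sites=list(dm))
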