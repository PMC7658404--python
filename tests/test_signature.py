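import numpy as np
import pandas as pd
import pytest

from reopairs.reo_screen import OrientedGenePair, pairs_to_frame
from reopairs.signature import (
    Signature,
    adapt_to_platform,
    classify,
    f_score,
    fd_cutoff_scan,
    optimize_vote_rule,
    redundancy_removal,
    train_signature,
    vote_count,
    vote_counts,
)
from reopairs.synthetic import SyntheticConfig, generate_cohort


def make_pairs(spec):
    """spec: list of (g_up, g_down, fd[, p])."""
    rows = []
    for item in spec:
        up, down, fd = item[:3]
        p = item[3] if len(item) > 3 else 1e-6
        rows.append(OrientedGenePair(up, down, fd, 0.0, fd, p, p))
    frame = pairs_to_frame(rows)
    frame["p1"] = frame["fd"]
    frame["p2"] = 0.0
    return frame


def greedy_oracle(frame):
    """Independent re-implementation of the per-gene largest-FD rule."""
    ordered = frame.sort_values(
        by=["fd", "p_value", "g_up", "g_down"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    used, kept = set(), []
    for _, row in ordered.iterrows():
        if row["g_up"] not in used and row["g_down"] not in used:
            kept.append((row["g_up"], row["g_down"]))
            used |= {row["g_up"], row["g_down"]}
    return kept


def vote_rule_oracle(votes, positive, m):
    """Exhaustive k scan re-implemented from the confusion matrix."""
    best = None
    for k in range(1, m + 1):
        tp = sum(1 for v, y in zip(votes, positive) if v >= k and y)
        fn = sum(1 for v, y in zip(votes, positive) if v < k and y)
        tn = sum(1 for v, y in zip(votes, positive) if v < k and not y)
        fp = sum(1 for v, y in zip(votes, positive) if v >= k and not y)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        f = 0.0 if sens + spec == 0 else 2 * sens * spec / (sens + spec)
        if best is None or f >= best[1]:
            best = (k, f)
    return best


class TestRedundancyRemoval:
    def test_shared_gene_loses_to_larger_fd(self):
        frame = make_pairs([("A", "B", 0.9), ("A", "C", 0.8), ("D", "E", 0.7)])
        kept = redundancy_removal(frame)
        assert list(zip(kept["g_up"], kept["g_down"])) == [("A", "B"), ("D", "E")]

    def test_greedy_chain(self):
        frame = make_pairs([("A", "B", 0.9), ("B", "C", 0.85), ("C", "D", 0.8)])
        kept = redundancy_removal(frame)
        assert list(zip(kept["g_up"], kept["g_down"])) == [("A", "B"), ("C", "D")]

    def test_matches_independent_greedy_on_random_pairs(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(50)]
        seen = set()
        spec = []
        while len(spec) < 200:
            u, d = rng.choice(genes, size=2, replace=False)
            if (u, d) in seen or (d, u) in seen:
                continue
            seen.add((u, d))
            spec.append((u, d, round(rng.uniform(0.1, 0.9), 3), rng.uniform(0, 1e-3)))
        frame = make_pairs(spec)
        kept = redundancy_removal(frame)
        assert list(zip(kept["g_up"], kept["g_down"])) == greedy_oracle(frame)
        flat = list(kept["g_up"]) + list(kept["g_down"])
        assert len(flat) == len(set(flat))

    def test_empty_input(self):
        frame = make_pairs([])
        assert len(redundancy_removal(frame)) == 0


class TestVoteCount:
    def test_all_patterns_satisfied(self):
        frame = make_pairs([("A", "B", 0.9), ("C", "D", 0.8)])
        sample = pd.Series({"A": 5.0, "B": 1.0, "C": 3.0, "D": 2.0})
        assert vote_count(sample, frame) == 2

    def test_all_ties_count_zero(self):
        frame = make_pairs([("A", "B", 0.9)])
        sample = pd.Series({"A": 2.0, "B": 2.0})
        assert vote_count(sample, frame) == 0

    def test_matches_per_pair_loop(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        frame = make_pairs(
            [(genes[2 * i], genes[2 * i + 1], 0.5) for i in range(10)]
        )
        sample = pd.Series(rng.normal(size=20), index=genes)
        expected = sum(
            1 for u, d in zip(frame["g_up"], frame["g_down"]) if sample[u] > sample[d]
        )
        assert vote_count(sample, frame) == expected

    def test_missing_gene_is_hard_error(self):
        frame = make_pairs([("A", "ZZZ", 0.9)])
        sample = pd.Series({"A": 1.0, "B": 2.0})
        with pytest.raises(KeyError, match="adapt"):
            vote_count(sample, frame)


class TestFScore:
    def test_validation_cohort_value(self):
        # perfect sensitivity with specificity 8/13
        assert f_score(1.0, 8 / 13) == pytest.approx(0.7619, abs=5e-4)

    def test_equal_inputs_fixed_point(self):
        for s in (0.0, 0.3, 1.0):
            assert f_score(s, s) == pytest.approx(s)

    def test_five_sixths_by_six_sevenths(self):
        assert f_score(5 / 6, 6 / 7) == pytest.approx(0.8451, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f_score(1.2, 0.5)


class TestOptimizeVoteRule:
    def test_perfect_separation_prefers_largest_k(self):
        votes = [10] * 5 + [0] * 7
        labels = [1] * 5 + [2] * 7
        k, f, sens, spec = optimize_vote_rule(votes, labels, 10)
        assert f == 1.0 and sens == 1.0 and spec == 1.0
        assert k == 10  # ties break toward the stricter rule

    def test_identical_votes_degenerate_split(self):
        votes = [4] * 10
        labels = [1] * 3 + [2] * 7
        k, f, sens, spec = optimize_vote_rule(votes, labels, 8)
        # any k <= 4 predicts all positive: sens 1, spec 0, F 0; k > 4 the reverse
        assert f == 0.0

    def test_matches_exhaustive_oracle_on_random_votes(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            m = int(rng.integers(3, 20))
            n = int(rng.integers(10, 60))
            votes = rng.integers(0, m + 1, size=n)
            labels = rng.permutation([1] * (n // 3 + 1) + [2] * (n - n // 3 - 1))
            k, f, _, _ = optimize_vote_rule(votes, labels, m)
            ok, of = vote_rule_oracle(votes, labels == 1, m)
            assert (k, f) == (ok, pytest.approx(of))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_vote_rule([1, 2], [1, 1], 3)


class TestFdCutoffScan:
    def _cohort_votesable(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame(
            rng.normal(size=(8, 12)), index=genes, columns=[f"s{i}" for i in range(12)]
        )
        labels = pd.Series([1] * 5 + [2] * 7, index=expr.columns)
        return expr, labels

    def test_grid_spans_31_points(self):
        expr, labels = self._cohort_votesable()
        frame = make_pairs(
            [(f"g{2*i}", f"g{2*i+1}", fd) for i, fd in enumerate([0.60, 0.71, 0.83, 0.90])]
        )
        _, records = fd_cutoff_scan(frame, expr, labels)
        assert len(records) == 31
        cutoffs = [r.fd_cutoff for r in records]
        assert cutoffs[0] == pytest.approx(0.90) and cutoffs[-1] == pytest.approx(0.60)

    def test_single_candidate(self):
        expr, labels = self._cohort_votesable()
        frame = make_pairs([("g0", "g1", 0.62)])
        sig, records = fd_cutoff_scan(frame, expr, labels)
        assert len(sig.pairs) == 1 and sig.k == 1
        assert len(records) == 1

    def test_winner_is_max_over_records_and_sizes_monotone(self, small_cohort):
        expr, labels, truth = small_cohort
        sig, records, _ = train_signature(expr, labels)
        best = max(r.best_f_score for r in records)
        assert sig.training_f_score == pytest.approx(best)
        sizes = [r.panel_size for r in records]  # cutoff descending
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_removal_stage_global_also_valid(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels, removal_stage="global")
        genes = [g for p in sig.pairs for g in (p.g_up, p.g_down)]
        assert len(genes) == len(set(genes))
        assert all(p.fd >= sig.fd_cutoff - 1e-12 for p in sig.pairs)


class TestClassify:
    def _signature(self):
        pairs = [
            OrientedGenePair("A", "B", 0.95, 0.05, 0.9),
            OrientedGenePair("C", "D", 0.9, 0.1, 0.8),
            OrientedGenePair("E", "F", 0.85, 0.15, 0.7),
        ]
        return Signature(pairs=pairs, k=2, fd_cutoff=0.7, training_f_score=1.0)

    def test_threshold_boundary(self):
        sig = self._signature()
        expr = pd.DataFrame(
            {
                "all3": [5, 1, 5, 1, 5, 1],
                "two": [5, 1, 5, 1, 1, 5],
                "one": [5, 1, 1, 5, 1, 5],
            },
            index=["A", "B", "C", "D", "E", "F"],
            dtype=float,
        )
        calls = classify(expr, sig)
        assert calls.loc["all3", "label"] == 1
        assert calls.loc["two", "label"] == 1
        assert calls.loc["one", "label"] == 2  # k-1 votes: negative
        assert list(calls["votes"]) == [3, 2, 1]

    def test_training_confusion_consistent_with_optimization(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        calls = classify(expr, sig)
        pos = labels == 1
        sens = ((calls["label"] == 1) & pos).sum() / pos.sum()
        spec = ((calls["label"] == 2) & ~pos).sum() / (~pos).sum()
        assert sig.training["sensitivity"] == pytest.approx(sens)
        assert sig.training["specificity"] == pytest.approx(spec)
        assert sig.training_f_score == pytest.approx(f_score(sens, spec))

    def test_invariant_to_non_signature_genes(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        keep = sorted(sig.genes())
        pd.testing.assert_frame_equal(
            classify(expr, sig), classify(expr.loc[keep], sig)
        )


class TestAdaptToPlatform:
    def test_all_genes_available_is_identity(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        adapted = adapt_to_platform(sig, expr.index, expr, labels)
        assert adapted is sig

    def test_reduced_panel_reoptimizes_k_to_oracle(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        if len(sig.pairs) < 3:
            drop_n = 1
        else:
            drop_n = 2
        dropped_genes = {sig.pairs[i].g_up for i in range(drop_n)}
        available = set(expr.index) - dropped_genes
        adapted = adapt_to_platform(sig, available, expr, labels)
        assert len(adapted.pairs) == len(sig.pairs) - drop_n
        votes = vote_counts(expr, pairs_to_frame(adapted.pairs)).to_numpy()
        ok, of = vote_rule_oracle(
            votes, (labels == 1).to_numpy(), len(adapted.pairs)
        )
        assert adapted.k == ok
        assert adapted.training_f_score == pytest.approx(of)

    def test_nothing_measurable_is_error(self, small_cohort):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        with pytest.raises(ValueError, match="platform"):
            adapt_to_platform(sig, {"not_a_gene"}, expr, labels)


class TestSignatureSerialization:
    def test_json_round_trip_reproduces_classification(self, small_cohort, tmp_path):
        expr, labels, _ = small_cohort
        sig, _, _ = train_signature(expr, labels)
        path = tmp_path / "sig.json"
        sig.save(path)
        loaded = Signature.load(path)
        assert loaded.k == sig.k
        assert loaded.fd_cutoff == sig.fd_cutoff
        assert loaded.pairs == sig.pairs
        pd.testing.assert_frame_equal(classify(expr, sig), classify(expr, loaded))

    def test_invariants_enforced(self):
        pairs = [OrientedGenePair("A", "B", 0.9, 0.1, 0.8)]
        with pytest.raises(ValueError):
            Signature(pairs=pairs, k=2, fd_cutoff=0.5, training_f_score=1.0)
        dup = pairs + [OrientedGenePair("A", "C", 0.9, 0.1, 0.8)]
        with pytest.raises(ValueError):
            Signature(pairs=dup, k=1, fd_cutoff=0.5, training_f_score=1.0)
        with pytest.raises(ValueError):
            Signature(pairs=pairs, k=1, fd_cutoff=0.95, training_f_score=1.0)
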