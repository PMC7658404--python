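"""Adapt a signature to a platform that does not measure all of its genes.

When a validation platform lacks some signature genes, the affected pairs
are dropped and the vote threshold k is re-optimized on the original
training cohort restricted to the surviving pairs — the threshold belongs
to the panel, so a smaller panel gets its own exhaustive k scan.
"""

from reopairs import (
    SyntheticConfig,
    adapt_to_platform,
    classify,
    confusion,
    generate_cohort,
    metrics_from_confusion,
    train_signature,
)

expr, labels, _ = generate_cohort(SyntheticConfig(seed=2))
sig, _, _ = train_signature(expr, labels)
print(f"full signature : {len(sig.pairs)} pairs, k = {sig.k}")

# simulate a platform missing the genes of the first two pairs
missing = {sig.pairs[0].g_up, sig.pairs[1].g_down} if len(sig.pairs) >= 2 else {
    sig.pairs[0].g_up
}
available = set(expr.index) - missing
adapted = adapt_to_platform(sig, available, expr, labels)
print(
    f"adapted        : {len(adapted.pairs)} pairs, k = {adapted.k} "
    f"(re-optimized on the training cohort)"
)

test_expr, test_labels, _ = generate_cohort(
    SyntheticConfig(n_pos=40, n_neg=80, seed=20002)
)
calls = classify(test_expr.drop(index=sorted(missing)), adapted)
m = metrics_from_confusion(confusion(calls["label"], test_labels))
print(
    f"held-out with reduced panel: sensitivity {m.sensitivity:.3f}, "
    f"specificity {m.specificity:.3f}, F {m.f:.3f}"
)
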