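"""Classifier stack: feature matrix, training-set construction, naive
Bayes semantics, cross-validation, and the six performance measures."""

import math

import numpy as np
import pandas as pd
import pytest

from isown import classify as clf
from isown.annotate import AnnotationRecord
from isown.classify import (
    ClassifierError,
    ConfusionCounts,
    FeatureSchema,
    SchemaError,
    balanced_sets,
    build_matrix,
    cross_validate,
    info_gain,
    metrics,
    predict,
    roc_auc,
    select_best,
    train,
    train_from_samples,
)
from tests.conftest import make_variant


# --- performance measures -----------------------------------------------------


def test_metrics_direct_formulas():
    rep = metrics(ConfusionCounts(tp=9, fn=1, fp=0, tn=10))
    assert rep.recall == pytest.approx(0.9)
    assert rep.precision == pytest.approx(1.0)
    assert rep.fpr == pytest.approx(0.0)
    assert rep.accuracy == pytest.approx(0.95)


def test_f1_harmonic_mean_fixed_point():
    rep = metrics(ConfusionCounts(tp=1, fn=1, fp=1, tn=1))
    assert rep.precision == rep.recall == 0.5
    assert rep.f1 == pytest.approx(0.5)


def test_metrics_match_independent_arithmetic_oracle():
    rng = np.random.default_rng(2)
    for _ in range(500):
        tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, size=4))
        if tp + fp + tn + fn == 0:
            continue
        rep = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if tp + fn:
            assert rep.recall == pytest.approx(tp / (tp + fn))
        else:
            assert rep.recall is None
        if tp + fp:
            assert rep.precision == pytest.approx(tp / (tp + fp))
        else:
            assert rep.precision is None
        if rep.precision is not None and rep.recall is not None and rep.precision + rep.recall:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            )
        if fp + tn:
            assert rep.fpr == pytest.approx(fp / (fp + tn))
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))


def test_undefined_measures_flagged_not_zeroed():
    rep = metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=10))
    assert rep.recall is None and rep.precision is None and rep.f1 is None
    assert rep.fpr == pytest.approx(0.0) and rep.accuracy == pytest.approx(1.0)
    # precision 0 (not None) when somatic calls exist but are all wrong
    rep = metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
    assert rep.precision == 0.0 and rep.recall is None and rep.f1 is None


def test_roc_auc_limits_and_brute_force():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], ["somatic", "somatic", "germline", "germline"]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], ["somatic", "somatic", "germline", "germline"]) == 0.5
    rng = np.random.default_rng(8)
    scores = rng.choice(np.linspace(0, 1, 25), size=200)  # many ties
    labels = rng.choice(["somatic", "germline"], size=200)
    pos = scores[labels == "somatic"]
    neg = scores[labels == "germline"]
    brute = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    ) / (len(pos) * len(neg))
    assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(ClassifierError):
        roc_auc([0.5], ["somatic"])


def test_select_best_auc_then_f1_then_name():
    def agg(auc, f1):
        return {"auc": {"mean": auc}, "f1": {"mean": f1}}

    assert select_best({"a": agg(0.99, 0.9), "b": agg(0.96, 0.95)}) == "a"
    assert select_best({"a": agg(0.9, 0.95), "b": agg(0.9, 0.93)}) == "a"
    assert select_best({"b": agg(0.9, 0.95), "a": agg(0.9, 0.95)}) == "a"
    assert select_best({"only": agg(0.5, 0.5)}) == "only"


# --- feature matrix -----------------------------------------------------------


def test_build_matrix_empty_and_missing_markers():
    m, labels = build_matrix([])
    assert list(m.columns) == list(clf.FEATURE_ORDER)
    assert len(m) == 0 and labels is None
    v = make_variant(flank_weight=None, context=None)
    m, labels = build_matrix([v])
    assert np.isnan(m.loc[0, "flank_weight"])
    assert m.loc[0, "context"] == "missing"
    assert labels is None  # unlabeled


def test_build_matrix_roundtrips_through_interchange_tsv(tmp_path):
    from isown.collapse import read_collapsed, write_collapsed

    rng = np.random.default_rng(9)
    variants = []
    for i in range(50):
        variants.append(
            make_variant(
                pos=10 + i,
                mean_vaf=float(rng.random()),
                flank_weight=None if i % 7 == 0 else float(rng.random()),
                sample_frequency=float(rng.uniform(0.01, 1)),
                ann=AnnotationRecord(
                    cnt=int(rng.integers(0, 50)),
                    in_exac=bool(rng.random() < 0.5),
                    in_dbsnp_rare=bool(rng.random() < 0.5),
                    ma_category=str(rng.choice(["high", "neutral", "missing"])),
                    pp2_category=str(rng.choice(["benign", "missing"])),
                ),
                context=str(rng.choice(["ACA", "TGT"])) if i % 5 else None,
                pattern=str(rng.choice(["CA", "TC"])),
                label=str(rng.choice(["somatic", "germline"])),
            )
        )
    path = tmp_path / "m.tsv"
    write_collapsed(variants, path)
    m1, y1 = build_matrix(variants)
    m2, y2 = build_matrix(read_collapsed(path))
    pd.testing.assert_frame_equal(m1, m2, check_exact=False)
    assert list(y1) == list(y2)


def test_unknown_level_mapped_to_missing_with_warning(caplog):
    schema = FeatureSchema()
    m, _ = build_matrix([make_variant()])
    m.loc[0, "ma_category"] = "weird_level"
    with caplog.at_level("WARNING"):
        cleaned = clf.sanitize_levels(m, schema)
    assert cleaned.loc[0, "ma_category"] == "missing"
    assert "unknown level" in caplog.text


# --- training sets ------------------------------------------------------------


def _labeled_pool(n_per_class=900, seed=0):
    rng = np.random.default_rng(seed)
    variants = []
    for i in range(2 * n_per_class):
        somatic = i < n_per_class
        variants.append(
            make_variant(
                pos=1000 + i,
                mean_vaf=float(np.clip(rng.normal(0.25 if somatic else 0.5, 0.07), 0.01, 0.99)),
                sample_frequency=float(rng.uniform(0.01, 0.1 if somatic else 0.8)),
                ann=AnnotationRecord(
                    cnt=int(rng.integers(0, 30)) if somatic else 0,
                    in_dbsnp_rare=bool(rng.random() < (0.02 if somatic else 0.7)),
                ),
                label="somatic" if somatic else "germline",
                # somatic alleles are private; germline ones recur across samples
                sample_ids=frozenset(
                    {f"s{rng.integers(10)}"}
                    if somatic
                    else {f"s{j}" for j in rng.choice(10, size=3, replace=False)}
                ),
            )
        )
    return variants


def test_balanced_sets_counts_and_determinism():
    variants = _labeled_pool()
    m, y = build_matrix(variants)
    y = y.to_numpy(dtype=object)
    sets = balanced_sets(m, y, n_sets=10, per_class=700, seed=5)
    assert len(sets) == 10
    for sm, sy in sets:
        assert (sy == "somatic").sum() == 700
        assert (sy == "germline").sum() == 700
        assert len(sm) == 1400
    again = balanced_sets(m, y, n_sets=10, per_class=700, seed=5)
    for (a, ya), (b, yb) in zip(sets, again):
        pd.testing.assert_frame_equal(a, b)
        assert list(ya) == list(yb)


def test_balanced_sets_reduced_to_minority_size(caplog):
    variants = _labeled_pool(n_per_class=50)
    m, y = build_matrix(variants)
    with caplog.at_level("WARNING"):
        sets = balanced_sets(m, y.to_numpy(dtype=object), n_sets=1, per_class=700, seed=0)
    assert len(sets[0][0]) == 100
    assert "reduced" in caplog.text


def test_train_from_samples_equal_classes_and_determinism():
    variants = _labeled_pool()
    chosen = [f"s{i}" for i in range(4)]
    a = train_from_samples(variants, chosen, seed=3)
    b = train_from_samples(variants, chosen, seed=3)
    n_som = sum(v.label == "somatic" for v in a)
    n_germ = sum(v.label == "germline" for v in a)
    assert n_som == n_germ > 0
    assert [v.key for v in a] == [v.key for v in b]
    for v in a:
        assert v.sample_ids & set(chosen)
    with pytest.raises(ClassifierError):
        train_from_samples([v for v in variants if v.label == "germline"], chosen)


# --- naive Bayes semantics ------------------------------------------------------


def _toy_variants():
    """Balanced 2-feature toy: one binary feature, one Gaussian feature;
    everything else constant (and therefore cancelling) or missing."""
    rows = [
        # germline: exac mostly true, vaf ~ 0.5
        (True, 0.50), (True, 0.45), (True, 0.55), (False, 0.50),
        # somatic: exac mostly false, vaf ~ 0.25
        (False, 0.20), (False, 0.25), (False, 0.30), (True, 0.25),
    ]
    variants = []
    for i, (exac, v) in enumerate(rows):
        variants.append(
            make_variant(
                pos=10 + i,
                mean_vaf=v,
                flank_weight=None,
                sample_frequency=0.1,
                ann=AnnotationRecord(cnt=0, in_exac=exac),
                label="germline" if i < 4 else "somatic",
            )
        )
    return variants


def test_naive_bayes_posterior_matches_hand_computation():
    variants = _toy_variants()
    m, y = build_matrix(variants)
    model = train("naive_bayes", m, y.to_numpy(dtype=object))
    query = make_variant(mean_vaf=0.4, flank_weight=None,
                         ann=AnnotationRecord(in_exac=True))
    qm, _ = build_matrix([query])
    _, scores = predict(model, qm)

    # closed-form oracle: balanced classes, so the prior and every
    # constant feature cancel; only in_exac (Laplace smoothed) and the
    # Gaussian mean_vaf term remain.
    def gauss(x, mu, var):
        return math.exp(-((x - mu) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)

    p_true_g = (3 + 1) / (4 + 2)
    p_true_s = (1 + 1) / (4 + 2)
    vafs_g = [0.50, 0.45, 0.55, 0.50]
    vafs_s = [0.20, 0.25, 0.30, 0.25]

    def moments(xs):
        mu = sum(xs) / len(xs)
        return mu, sum((x - mu) ** 2 for x in xs) / len(xs)

    mu_g, var_g = moments(vafs_g)
    mu_s, var_s = moments(vafs_s)
    lik_g = p_true_g * gauss(0.4, mu_g, var_g)
    lik_s = p_true_s * gauss(0.4, mu_s, var_s)
    expected = lik_s / (lik_s + lik_g)
    assert scores[0] == pytest.approx(expected, abs=1e-9)


def test_naive_bayes_omits_missing_continuous_features():
    variants = _toy_variants()
    m, y = build_matrix(variants)
    model = train("naive_bayes", m, y.to_numpy(dtype=object))
    with_vaf = make_variant(mean_vaf=0.25, flank_weight=None,
                            ann=AnnotationRecord(in_exac=False))
    # flank_weight is NaN in training and at predict time: omitting it
    # must leave the posterior well-defined and in (0, 1)
    qm, _ = build_matrix([with_vaf])
    _, s = predict(model, qm)
    assert 0.0 < s[0] < 1.0
    assert s[0] > 0.5  # low VAF, not in exome database -> somatic-leaning


def test_separable_training_set_perfectly_learned():
    rng = np.random.default_rng(4)
    variants = []
    for i in range(200):
        somatic = i % 2 == 0
        variants.append(
            make_variant(
                pos=10 + i,
                ann=AnnotationRecord(cnt=int(rng.integers(1, 50)) if somatic else 0),
                mean_vaf=0.3,
                label="somatic" if somatic else "germline",
            )
        )
    m, y = build_matrix(variants)
    model = train("naive_bayes", m, y.to_numpy(dtype=object))
    labels, _ = predict(model, m)
    assert (labels == y.to_numpy(dtype=object)).mean() == 1.0


def test_predict_contracts():
    variants = _toy_variants()
    m, y = build_matrix(variants)
    model = train("naive_bayes", m, y.to_numpy(dtype=object))
    empty, _ = build_matrix([])
    labels, scores = predict(model, empty)
    assert len(labels) == len(scores) == 0
    # re-scoring training vectors is deterministic
    l1, s1 = predict(model, m)
    l2, s2 = predict(model, m)
    assert np.array_equal(s1, s2)
    # hard labels equal thresholding at 0.5
    assert all((s >= 0.5) == (l == "somatic") for l, s in zip(l1, s1))
    with pytest.raises(SchemaError):
        predict(model, m[["cnt", "mean_vaf"]])


def test_single_class_training_fatal():
    variants = [v for v in _toy_variants() if v.label == "somatic"]
    m, y = build_matrix(variants)
    with pytest.raises(ClassifierError):
        train("naive_bayes", m, y.to_numpy(dtype=object))


@pytest.mark.parametrize("kind", ["tree_ensemble", "boosted_tree", "logistic"])
def test_sklearn_kinds_learn_separable_data(kind):
    variants = _labeled_pool(n_per_class=150, seed=1)
    m, y = build_matrix(variants)
    y = y.to_numpy(dtype=object)
    model = train(kind, m, y, seed=0)
    labels, scores = predict(model, m)
    assert (labels == y).mean() > 0.9
    assert roc_auc(scores, y) > 0.95


# --- cross-validation -----------------------------------------------------------


def test_cross_validation_separable_limit():
    variants = []
    rng = np.random.default_rng(6)
    for i in range(300):
        somatic = i % 2 == 0
        variants.append(
            make_variant(
                pos=10 + i,
                ann=AnnotationRecord(cnt=int(rng.integers(1, 50)) if somatic else 0),
                label="somatic" if somatic else "germline",
            )
        )
    m, y = build_matrix(variants)
    sets = balanced_sets(m, y.to_numpy(dtype=object), n_sets=2, per_class=100, seed=0)
    reports, aggregate = cross_validate("naive_bayes", sets, seed=0)
    assert aggregate["f1"]["mean"] == pytest.approx(1.0)
    assert aggregate["fpr"]["mean"] == pytest.approx(0.0)


def test_cross_validation_reproducible():
    variants = _labeled_pool(n_per_class=120, seed=2)
    m, y = build_matrix(variants)
    sets = balanced_sets(m, y.to_numpy(dtype=object), n_sets=3, per_class=80, seed=1)
    _, agg1 = cross_validate("naive_bayes", sets, seed=9)
    _, agg2 = cross_validate("naive_bayes", sets, seed=9)
    assert agg1["f1"]["mean"] == agg2["f1"]["mean"]
    assert agg1["auc"]["mean"] == agg2["auc"]["mean"]


def test_label_shuffled_auc_near_half():
    rng = np.random.default_rng(13)
    variants = _labeled_pool(n_per_class=400, seed=3)
    labels = np.array([v.label for v in variants], dtype=object)
    rng.shuffle(labels)
    for v, lab in zip(variants, labels):
        v.label = str(lab)
    m, y = build_matrix(variants)
    sets = balanced_sets(m, y.to_numpy(dtype=object), n_sets=15, per_class=150, seed=2)
    _, agg = cross_validate("naive_bayes", sets, seed=2)
    assert 0.43 <= agg["auc"]["mean"] <= 0.57


# --- information gain -----------------------------------------------------------


def test_info_gain_limits():
    labels = ["somatic"] * 50 + ["germline"] * 50
    identical = ["a"] * 50 + ["b"] * 50
    assert info_gain(identical, labels) == pytest.approx(1.0)
    assert info_gain(["x"] * 100, labels) == pytest.approx(0.0)


def test_info_gain_matches_contingency_oracle():
    rng = np.random.default_rng(21)
    levels = np.array(["a", "b", "c", "d"])
    col = rng.choice(levels, size=500)
    # labels correlated with the feature
    p_somatic = {"a": 0.9, "b": 0.6, "c": 0.3, "d": 0.1}
    labels = np.array(
        ["somatic" if rng.random() < p_somatic[c] else "germline" for c in col],
        dtype=object,
    )

    def entropy(counts):
        total = sum(counts)
        return -sum(c / total * math.log2(c / total) for c in counts if c)

    y = labels == "somatic"
    h = entropy([y.sum(), (~y).sum()])
    h_cond = 0.0
    for lvl in levels:
        mask = col == lvl
        h_cond += mask.mean() * entropy([y[mask].sum(), (~y[mask]).sum()])
    assert info_gain(col, labels) == pytest.approx(h - h_cond, abs=1e-12)


def test_info_gain_non_negative_on_continuous():
    rng = np.random.default_rng(30)
    x = rng.normal(size=400)
    x[::13] = np.nan
    labels = np.where(rng.random(400) < 0.5, "somatic", "germline")
    assert info_gain(x, labels) >= 0.0
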