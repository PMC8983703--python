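"""Class rules, bagged SVM, fold assignment and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zernsurf.classify import (
    ConfusionCounts,
    SSContent,
    UndefinedMetricError,
    assign_class_rule,
    assign_fold,
    metrics,
    ss_content_from_structure,
    train_bagged_svm,
)
from zernsurf.fixtures import make_descriptor_clusters, make_ideal_helix, make_ideal_sheet
from zernsurf.similarity import zdzd_score


class TestClassRules:
    @pytest.mark.parametrize(
        "length,helix,sheet,rule,expected",
        [
            (40, 0.9, 0.0, "original", "small"),
            (100, 0.60, 0.05, "original", "alpha"),
            (100, 0.10, 0.40, "original", "beta"),
            (100, 0.30, 0.30, "original", "alphabeta"),
            (100, 0.25, 0.40, "original", "alphabeta"),  # helix cap blocks beta
            (52, 0.70, 0.0, "optimized", "small"),
            (60, 0.55, 0.0, "optimized", "alpha"),
            (60, 0.55, 0.0, "original", "alphabeta"),  # below 60% helix cutoff
            (100, 0.10, 0.25, "optimized", "beta"),
            (100, 0.10, 0.25, "original", "alphabeta"),  # below 35% sheet cutoff
        ],
    )
    def test_cascade_branches(self, length, helix, sheet, rule, expected):
        assert assign_class_rule(SSContent(length, helix, sheet), rule) == expected

    @pytest.mark.parametrize("rule", ["original", "optimized"])
    def test_cascade_is_total_on_grid_sweep(self, rule):
        # 5%-step sweep: every (length, helix, sheet) combination gets
        # exactly one label, and the cascade branch conditions partition
        # the space in the stated priority order
        for length in range(0, 201, 5):
            for h in np.arange(0, 1.0001, 0.05):
                for s in np.arange(0, 1.0001 - h, 0.05):
                    c = SSContent(length, float(h), float(s))
                    label = assign_class_rule(c, rule)
                    len_cut = 50 if rule == "original" else 55
                    helix_cut = 0.60 if rule == "original" else 0.55
                    sheet_cut = 0.35 if rule == "original" else 0.25
                    if length < len_cut:
                        assert label == "small"
                    elif h >= helix_cut:
                        assert label == "alpha"
                    elif s >= sheet_cut and h < 0.20:
                        assert label == "beta"
                    else:
                        assert label == "alphabeta"


class TestMetrics:
    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0)) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        acc, p, r, f = metrics(ConfusionCounts(TP=3, FP=1, TN=5, FN=1))
        assert (acc, p, r, f) == (0.8, 0.75, 0.75, 0.75)

    def test_undefined_precision_raises_naming_metric(self):
        with pytest.raises(UndefinedMetricError, match="precision"):
            metrics(ConfusionCounts(TP=0, FP=0, TN=9, FN=1))

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        st.integers(1, 500), st.integers(1, 500), st.integers(0, 500), st.integers(0, 500)
    )
    def test_formulas_against_direct_arithmetic(self, tp, fp, tn, fn):
        acc, p, r, f = metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
        assert acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / (tp + fn))
        if p + r > 0:
            assert f == pytest.approx(2 * p * r / (p + r))
            # F is the harmonic mean, hence between min and max of (P, R)
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


def class_clusters(rng, n_per_class=60):
    """Well-separated synthetic (SSContent, label) training data."""
    data = []
    for _ in range(n_per_class):
        data.append((SSContent(int(rng.integers(20, 45)), 0.3, 0.1), "small"))
        data.append(
            (SSContent(int(rng.integers(80, 300)), float(rng.uniform(0.7, 0.95)),
                       float(rng.uniform(0, 0.05))), "alpha")
        )
        data.append(
            (SSContent(int(rng.integers(80, 300)), float(rng.uniform(0, 0.1)),
                       float(rng.uniform(0.45, 0.8))), "beta")
        )
        data.append(
            (SSContent(int(rng.integers(80, 300)), float(rng.uniform(0.3, 0.45)),
                       float(rng.uniform(0.25, 0.4))), "alphabeta")
        )
    return data


class TestBaggedSVM:
    def test_recovers_separable_classes(self):
        rng = np.random.default_rng(0)
        data = class_clusters(rng)
        ensemble = train_bagged_svm(data, seed=1)
        pred = ensemble.predict([c for c, _ in data])
        acc = np.mean([p == lab for p, (_, lab) in zip(pred, data)])
        assert acc > 0.95

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(0)
        data = class_clusters(rng, n_per_class=40)
        queries = [c for c, _ in data[:40]]
        p1 = train_bagged_svm(data, seed=5).predict(queries)
        p2 = train_bagged_svm(data, seed=5).predict(queries)
        assert p1 == p2

    def test_shuffled_labels_drop_to_chance(self):
        rng = np.random.default_rng(1)
        data = class_clusters(rng)
        labels = [lab for _, lab in data]
        shuffled = list(rng.permutation(labels))
        # keep all four classes present after shuffling
        noisy = [(c, lab) for (c, _), lab in zip(data, shuffled)]
        ensemble = train_bagged_svm(noisy, seed=2)
        holdout = class_clusters(np.random.default_rng(9), n_per_class=30)
        pred = ensemble.predict([c for c, _ in holdout])
        acc = np.mean([p == lab for p, (_, lab) in zip(pred, holdout)])
        assert 0.1 <= acc <= 0.45

    def test_fewer_than_four_classes_rejected(self):
        data = [(SSContent(100, 0.8, 0.0), "alpha")] * 10 + [
            (SSContent(100, 0.0, 0.6), "beta")
        ] * 10
        with pytest.raises(ValueError):
            train_bagged_svm(data)


@pytest.fixture(scope="module")
def catalogue():
    descs, labels = make_descriptor_clusters(
        n_folds=5, per_fold=15, separation=1.0, noise=0.05, seed=13
    )
    cat = {}
    for d, lab in zip(descs, labels):
        cat.setdefault(lab, []).append(d)
    return cat


class TestAssignFold:
    @staticmethod
    def scorer(a, b):
        return zdzd_score(a, b).value

    def test_single_fold_catalogue(self, catalogue):
        fold = dict(list(catalogue.items())[:1])
        label, score = assign_fold(
            fold[next(iter(fold))][0], fold, scorer=self.scorer, seed=0
        )
        assert label.fold_id == next(iter(fold))

    def test_exemplar_query_finds_own_fold(self, catalogue):
        for fold_id, members in catalogue.items():
            label, score = assign_fold(members[0], catalogue, scorer=self.scorer, seed=1)
            assert label.fold_id == fold_id

    def test_recovery_accuracy_on_held_out_queries(self, catalogue):
        descs, labels = make_descriptor_clusters(
            n_folds=5, per_fold=10, separation=1.0, noise=0.05, seed=14
        )
        # same centers only when seed matches; rebuild queries from the
        # catalogue's own clusters instead: hold out 5 members per fold
        held = {f: members[10:] for f, members in catalogue.items()}
        train_cat = {f: members[:10] for f, members in catalogue.items()}
        correct = total = 0
        for f, queries in held.items():
            for q in queries:
                label, _ = assign_fold(q, train_cat, scorer=self.scorer, seed=2)
                correct += label.fold_id == f
                total += 1
        assert correct / total > 0.9

    def test_accuracy_degrades_with_noise(self):
        accs = []
        for noise in [0.05, 0.4, 1.2]:
            descs, labels = make_descriptor_clusters(
                n_folds=4, per_fold=12, separation=1.0, noise=noise, seed=21
            )
            cat, held = {}, {}
            for d, lab in zip(descs, labels):
                (cat if len(cat.get(lab, [])) < 8 else held).setdefault(lab, []).append(d)
            correct = total = 0
            for f, queries in held.items():
                for q in queries:
                    label, _ = assign_fold(q, cat, scorer=self.scorer, seed=3)
                    correct += label.fold_id == f
                    total += 1
            accs.append(correct / total)
        assert accs[0] >= accs[1] >= accs[2] or accs[0] > accs[2]

    def test_empty_catalogue_raises(self):
        with pytest.raises(ValueError):
            assign_fold(None, {}, scorer=self.scorer)


class TestSSContent:
    def test_ideal_helix_is_helical(self):
        c = ss_content_from_structure(make_ideal_helix(30))
        assert c.helix_frac > 0.8
        assert c.sheet_frac < 0.1

    def test_ideal_sheet_is_strandy(self):
        c = ss_content_from_structure(make_ideal_sheet(2, 10))
        assert c.sheet_frac > 0.6
        assert c.helix_frac < 0.1

    def test_random_coil_is_neither_helix_nor_sheet_rich(self):
        from zernsurf.structure_io import Atom, Structure

        rng = np.random.default_rng(8)
        pts = [np.zeros(3)]
        d = np.array([1.0, 0, 0])
        for _ in range(49):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            ang = rng.uniform(0.3, 1.2)
            d = (
                d * np.cos(ang)
                + np.cross(ax, d) * np.sin(ang)
                + ax * np.dot(ax, d) * (1 - np.cos(ang))
            )
            d /= np.linalg.norm(d)
            pts.append(pts[-1] + 3.8 * d)
        s = Structure(
            id="coil",
            atoms=[Atom("C", "CA", tuple(p), i + 1, "A", 50.0) for i, p in enumerate(pts)],
        )
        c = ss_content_from_structure(s)
        assert c.helix_frac < 0.2

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            ss_content_from_structure(make_ideal_helix(5).__class__(id="x", atoms=[]))
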