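"""Split arithmetic, patch extraction, dictionary learning and evaluation."""

import numpy as np
import pytest

from tprm.io import RunConfig
from tprm.pipeline import case_features
from tprm.progression import (
    PatchSet,
    classify_case,
    classify_patches,
    evaluate,
    extract_patches,
    logistic_baseline,
    mrmr_rank,
    stability_analysis,
    stratified_split,
    train_dictionaries,
)
from tprm.synthetic import PhantomSpec, generate_phantom
from tprm.prm import CLASS_CODES, classify_voxels
from tprm.topology import compute_tprm


def _make_patchset(X, edge=1, channels=("V_Norm",)):
    X = np.asarray(X, dtype=float)
    n = len(X)
    return PatchSet(patches=X, patch_edge_vox=edge, channels=channels,
                    locations=np.zeros((n, 3), dtype=int),
                    case_ids=np.array(["c"] * n))


class TestStratifiedSplit:
    def test_cohort_scale_counts(self):
        labels = np.array(["fast"] * 1516 + ["slow"] * 2967)
        train, test = stratified_split(labels, 0.35, seed=0)
        assert (labels[train] == "fast").sum() == 531
        assert (labels[train] == "slow").sum() == 1038
        assert (labels[test] == "fast").sum() == 985
        assert (labels[test] == "slow").sum() == 1929
        # disjoint and exhaustive
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 4483

    def test_even_split(self):
        labels = np.array(["fast"] * 10 + ["slow"] * 10)
        train, test = stratified_split(labels, 0.5, seed=1)
        assert (labels[train] == "fast").sum() == 5
        assert (labels[train] == "slow").sum() == 5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            stratified_split(np.array(["fast"] * 5), 0.35, 0)


@pytest.fixture(scope="module")
def phantom_maps():
    spec = PhantomSpec(class_fractions={"fSAD": 0.25}, coalescence=0.3, seed=21)
    ct, truth = generate_phantom(spec)
    prm = classify_voxels(ct)
    return compute_tprm(prm.labels, ct.lung_mask, CLASS_CODES)


class TestExtractPatches:
    def test_contract_and_determinism(self, phantom_maps):
        ps1 = extract_patches(phantom_maps, n_patches=100, patch_edge_vox=7, seed=5)
        ps2 = extract_patches(phantom_maps, n_patches=100, patch_edge_vox=7, seed=5)
        assert len(ps1) == 100
        assert ps1.patches.shape == (100, 7**3 * 4)
        assert (ps1.patches == ps2.patches).all()
        assert (ps1.locations == ps2.locations).all()
        # every patch covers >= 50% lung
        mask = phantom_maps.lung_mask
        for loc in ps1.locations:
            sl = tuple(slice(c - 3, c + 4) for c in loc)
            assert mask[sl].mean() >= 0.5

    def test_constant_maps_give_identical_patches(self, phantom_maps):
        import copy
        maps = copy.copy(phantom_maps)
        maps.V = {k: np.full_like(v, 0.5) for k, v in maps.V.items()}
        maps.chi = {k: np.zeros_like(v) for k, v in maps.chi.items()}
        ps = extract_patches(maps, n_patches=10, patch_edge_vox=5, seed=0)
        assert np.allclose(ps.patches, ps.patches[0])

    def test_lung_too_small_errors(self, phantom_maps):
        with pytest.raises(ValueError):
            extract_patches(phantom_maps, n_patches=5, patch_edge_vox=91, seed=0)


class TestDictionaryLearning:
    def test_representable_data_reaches_zero_error(self):
        rng = np.random.default_rng(0)
        # signals spanned by k orthonormal atoms
        k, d, n = 4, 16, 200
        basis = np.linalg.qr(rng.normal(size=(d, k)))[0]
        X = (basis @ rng.normal(size=(k, n))).T
        ps = _make_patchset(X, edge=1, channels=tuple(f"ch{i}" for i in range(d)))
        # same data as both classes; we only check reconstruction
        model = train_dictionaries(ps, ps, n_atoms=k, T=4, n_iter=25, seed=0)
        assert model.objective_fast[-1] < 1e-8

    def test_zero_iterations_returns_seeded_patches(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        ps = _make_patchset(X, channels=tuple(f"c{i}" for i in range(8)))
        model = train_dictionaries(ps, ps, n_atoms=6, T=2, n_iter=0, seed=3)
        assert np.allclose(np.linalg.norm(model.dict_fast, axis=0), 1.0)
        # every atom is a normalised training patch
        Xs = model.scale_patches(X)
        normed = Xs / np.linalg.norm(Xs, axis=1, keepdims=True)
        for atom in model.dict_fast.T:
            assert np.isclose(np.abs(normed @ atom), 1.0, atol=1e-8).any()

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 20))
        ps = _make_patchset(X, channels=tuple(f"c{i}" for i in range(20)))
        model = train_dictionaries(ps, ps, n_atoms=10, T=3, n_iter=15, seed=0)
        obj = np.array(model.objective_fast)
        assert (np.diff(obj) <= 1e-9).all()

    def test_separated_populations_classified_by_residual(self):
        # the two Gaussian patch populations live in orthogonal subspaces,
        # so each class dictionary reconstructs its own class far better
        rng = np.random.default_rng(3)
        d, k = 12, 3
        Q = np.linalg.qr(rng.normal(size=(d, 2 * k)))[0]
        fast = (Q[:, :k] @ rng.normal(size=(k, 300))).T
        slow = (Q[:, k:] @ rng.normal(size=(k, 300))).T
        chans = tuple(f"c{i}" for i in range(d))
        model = train_dictionaries(
            _make_patchset(fast[:200], channels=chans),
            _make_patchset(slow[:200], channels=chans),
            n_atoms=20, T=3, n_iter=10, seed=0)
        pred_fast = classify_patches(model, fast[200:])
        pred_slow = classify_patches(model, slow[200:])
        assert pred_fast.mean() >= 0.9
        assert (~pred_slow).mean() >= 0.9

    def test_atom_patch_classified_with_zero_residual_and_ties_to_slow(self):
        from tprm.progression import DictionaryModel
        rng = np.random.default_rng(4)
        D = np.linalg.qr(rng.normal(size=(6, 4)))[0]
        model = DictionaryModel(dict_fast=D.copy(), dict_slow=D.copy(),
                                sparsity=2, channel_scales=np.ones(1),
                                channels=("c",), patch_edge_vox=1)
        # a patch equal to an atom has zero residual under either dictionary;
        # ties break toward slow
        assert not classify_patches(model, D.T.copy()).any()

    def test_n_atoms_exceeding_patches_errors(self):
        X = np.ones((4, 3))
        ps = _make_patchset(X, channels=("a", "b", "c"))
        with pytest.raises(ValueError):
            train_dictionaries(ps, ps, n_atoms=10, T=1, n_iter=1)


class TestCaseAggregation:
    def test_extremes_and_threshold(self):
        from tprm.progression import DictionaryModel
        model = DictionaryModel(np.eye(2), np.eye(2), 1, np.ones(1), ("c",), 1,
                                aggregation_threshold=0.5)
        assert classify_case(model, np.ones(10, bool)) == (1.0, "fast")
        assert classify_case(model, np.zeros(10, bool)) == (0.0, "slow")
        score, label = classify_case(model, np.array([True, False, True, False]))
        assert score == 0.5 and label == "fast"
        with pytest.raises(ValueError):
            classify_case(model, np.array([], dtype=bool))


class TestEvaluate:
    def test_perfect_ranking(self):
        ev = evaluate([True, True, False, False], [0.9, 0.8, 0.2, 0.1])
        assert ev.auc == pytest.approx(1.0)
        assert ev.accuracy == 1.0

    def test_pairwise_enumerated_auc(self):
        # positives (0.9, 0.4) vs negatives (0.6, 0.1): 3 of 4 pairs ranked right
        ev = evaluate([True, True, False, False], [0.9, 0.4, 0.6, 0.1])
        assert ev.auc == pytest.approx(0.75)

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(0)
        y = rng.random(10_000) < 0.5
        ev = evaluate(y, rng.random(10_000))
        assert ev.auc == pytest.approx(0.5, abs=0.02)

    def test_confusion_matrix_at_threshold(self):
        ev = evaluate([True, True, False, False], [0.9, 0.4, 0.6, 0.1],
                      threshold=0.5)
        assert ev.confusion.tolist() == [[1, 1], [1, 1]]
        assert ev.sensitivity == 0.5 and ev.specificity == 0.5

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError):
            evaluate([True, True], [0.1, 0.2])


class TestMrmr:
    def test_label_copy_ranked_first_and_duplicate_penalized(self):
        rng = np.random.default_rng(0)
        n = 600
        y = rng.integers(0, 2, n)
        informative = y + rng.normal(0, 0.1, n)
        dup = informative + rng.normal(0, 0.01, n)
        other = y + rng.normal(0, 0.4, n)        # informative, not redundant
        noise = rng.normal(size=n)
        X = np.column_stack([informative, dup, other, noise])
        ranked = mrmr_rank(X, y, feature_names=["info", "dup", "other", "noise"])
        names = [r[0] for r in ranked]
        assert names[0] == "info"
        assert names.index("other") < names.index("dup")
        # without the redundant copy, pure noise ranks last
        ranked2 = mrmr_rank(np.column_stack([informative, other, noise]), y,
                            feature_names=["info", "other", "noise"])
        assert [r[0] for r in ranked2] == ["info", "other", "noise"]

    def test_constant_feature_last(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        X = np.column_stack([y + rng.normal(0, 0.2, 400), np.ones(400)])
        ranked = mrmr_rank(X, y, feature_names=["sig", "const"])
        assert ranked[-1][0] == "const"

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            mrmr_rank(np.ones((10, 1)), np.zeros(10))


class TestLogisticBaseline:
    def test_separable_and_null_means(self):
        rng = np.random.default_rng(0)
        n = 400
        y = np.array(["fast"] * 150 + ["slow"] * 250)
        sep = np.where(y == "fast", 1.0, -1.0)[:, None] + rng.normal(0, 0.05, (n, 4))
        train = np.arange(0, n, 2)
        test = np.arange(1, n, 2)
        ev, _, _ = logistic_baseline(sep, y, train, test)
        assert ev.auc > 0.99
        null = rng.normal(size=(n, 4))
        ev0, _, _ = logistic_baseline(null, y, train, test)
        assert abs(ev0.auc - 0.5) < 0.12


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = RunConfig(patches_per_case=25, patch_edge_vox=5, n_atoms=12,
                    n_iter=5, seed=0)
    feats, labels = [], []
    for i, (frac, lab) in enumerate([(0.05, "slow"), (0.22, "fast")] * 6):
        spec = PhantomSpec(class_fractions={"fSAD": frac},
                           coalescence=0.2 if lab == "slow" else 0.6,
                           seed=100 + i)
        feats.append(case_features(spec, f"c{i}", cfg, patch_seed=i))
        labels.append(lab)
    return feats, np.array(labels)


class TestStability:
    def test_run_count_and_gaussian_fit(self, tiny_setup):
        from tprm.progression import _concat_patchsets
        feats, labels = tiny_setup
        train_fast = _concat_patchsets(
            [f.patches for f, l in zip(feats[:8], labels[:8]) if l == "fast"])
        train_slow = _concat_patchsets(
            [f.patches for f, l in zip(feats[:8], labels[:8]) if l == "slow"])
        out = stability_analysis(
            train_fast, train_slow,
            [f.patches for f in feats[8:]], labels[8:],
            channels=("V_fSAD", "chi_fSAD"), n_runs=4,
            n_atoms=10, T=2, n_iter=3, seed=0)
        for ch in ("V_fSAD", "chi_fSAD"):
            assert len(out[ch]["accuracies"]) == 4
            assert out[ch]["sd"] >= 0
            assert 0 <= out[ch]["mean"] <= 1
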