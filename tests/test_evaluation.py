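"""Validation protocols, confusion matrices, MI maps, noise sweep."""

import numpy as np
import pytest

from dadpc.evaluation import (
    ProtocolSpec,
    confusion,
    mutual_info_map,
    noise_sweep,
    run_protocol,
)
from dadpc.synthetic import SyntheticRecipe, generate
from dadpc.trainer import DomainDataset, TrainConfig


class TestFolds:
    def test_cuse_has_one_fold_per_subject(self, easy_manifest):
        folds = list(ProtocolSpec("CUSE").folds(easy_manifest))
        assert len(folds) == 15
        for src_keys, tgt_keys, _ in folds:
            assert all(sess == 0 for _, sess in src_keys + tgt_keys)
            assert len(tgt_keys) == 1
            tgt_subj = tgt_keys[0][0]
            assert all(s != tgt_subj for s, _ in src_keys)

    def test_cuce_holds_out_all_sessions_of_one_subject(self, easy_manifest):
        folds = list(ProtocolSpec("CUCE").folds(easy_manifest))
        assert len(folds) == 15
        src_keys, tgt_keys, _ = folds[0]
        assert sorted(tgt_keys) == [(0, 0), (0, 1), (0, 2)]
        assert len(src_keys) == 14 * 3
        # per-session granularity triples the fold count
        assert len(list(ProtocolSpec("CUCE", per_session_folds=True).folds(easy_manifest))) == 45

    def test_wuce_uses_first_two_sessions_as_source(self, easy_manifest):
        folds = list(ProtocolSpec("WUCE").folds(easy_manifest))
        assert len(folds) == 15
        for src_keys, tgt_keys, _ in folds:
            subj = tgt_keys[0][0]
            assert src_keys == [(subj, 0), (subj, 1)]
            assert tgt_keys == [(subj, 2)]

    def test_folds_are_disjoint_and_cover_manifest(self, easy_manifest):
        for name in ("CUSE", "CUCE", "WUCE"):
            seen_targets = []
            for src_keys, tgt_keys, _ in ProtocolSpec(name).folds(easy_manifest):
                assert not set(src_keys) & set(tgt_keys)
                seen_targets.extend(tgt_keys)
            assert len(seen_targets) == len(set(seen_targets))

    def test_cdcv_requires_second_dataset(self, easy_manifest):
        with pytest.raises(ValueError):
            list(ProtocolSpec("CDCV").folds(easy_manifest))

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec("LOSO")


class TestRunProtocol:
    def test_perfect_separability_gives_pacc_100(self, easy_manifest, light_config):
        res = run_protocol(easy_manifest, ProtocolSpec("WUCE"), light_config)
        assert res.mean == pytest.approx(100.0)
        assert res.std == pytest.approx(0.0)
        assert np.all(res.confusion == np.diag(np.diag(res.confusion)))

    def test_confusion_rows_conserve_class_counts(self, easy_manifest, light_config):
        res = run_protocol(easy_manifest, ProtocolSpec("WUCE"), light_config)
        per_class = 8 * 15  # n_per_class x subjects, one session each
        assert list(res.confusion.sum(axis=1)) == [per_class] * 3

    def test_mean_is_arithmetic_mean_of_folds(self, easy_manifest, light_config):
        res = run_protocol(easy_manifest, ProtocolSpec("CUSE"), light_config)
        assert res.mean == pytest.approx(np.mean(res.fold_accuracies), abs=1e-12)

    def test_cdcv_single_fold(self, light_config):
        a = generate(SyntheticRecipe(n_subjects=2, n_per_class=10, d=8, class_sep=10.0,
                                     outlier_fraction=0.0, seed=1))
        b = generate(SyntheticRecipe(n_subjects=2, n_per_class=10, d=8, class_sep=10.0,
                                     outlier_fraction=0.0, seed=2))
        res = run_protocol(a, ProtocolSpec("CDCV"), light_config, other=b)
        assert len(res.fold_accuracies) == 1


class TestConfusion:
    def test_hand_case(self):
        cm = confusion([0, 0, 1], [0, 1, 1], 2)
        assert np.array_equal(cm, [[1, 1], [0, 1]])

    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.integers(0, 4, 50)
        cm = confusion(y, y, 4)
        assert np.array_equal(cm, np.diag(np.bincount(y, minlength=4)))

    def test_constant_prediction_single_column(self, rng):
        y = rng.integers(0, 3, 30)
        cm = confusion(y, np.zeros(30, int), 3)
        assert cm[:, 1:].sum() == 0
        assert list(cm[:, 0]) == list(np.bincount(y, minlength=3))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 2)


class TestMutualInfoMap:
    def test_shape_and_bounds(self, rng):
        X = rng.normal(size=(150, 6))
        P = rng.dirichlet(np.ones(3), size=150)
        I = mutual_info_map(X, P, seed=0)
        assert I.shape == (3, 6)
        assert I.min() >= 0 and I.max() <= 1

    def test_discrete_identity_feature_has_mi_log2(self, rng):
        """A feature equal to the class index (plus tiny jitter) carries
        ln 2 nats about a balanced binary prediction."""
        from sklearn.feature_selection import mutual_info_classif

        y = np.tile([0, 1], 300)
        X = y[:, None] + rng.normal(0, 1e-3, size=(600, 1))
        raw = mutual_info_classif(X, y, n_neighbors=3, random_state=0)
        assert raw[0] == pytest.approx(np.log(2.0), abs=0.05)

    def test_independent_feature_scores_near_zero(self, rng):
        y = rng.integers(0, 2, 400)
        X = np.column_stack([rng.normal(size=400), y + rng.normal(0, 1e-3, 400)])
        I = mutual_info_map(X, np.eye(2)[y], seed=0)
        # scaled map: informative column ~1, independent column ~0
        assert I[:, 1].max() == pytest.approx(1.0)
        assert I[:, 0].max() < 0.1

    def test_misaligned_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            mutual_info_map(rng.normal(size=(10, 2)), rng.dirichlet([1, 1], size=9))


def test_noise_sweep_reports_all_levels_and_eta0_matches_plain_run():
    ds = generate(SyntheticRecipe(n_subjects=2, n_per_class=15, d=8, class_sep=8.0,
                                  outlier_fraction=0.0, seed=6))
    src = DomainDataset(ds.X[(0, 0)], ds.y[(0, 0)])
    tgt = DomainDataset(ds.X[(1, 0)], ds.y[(1, 0)])
    cfg = TrainConfig(seed=0, max_epochs=20, warmup_epochs=8, hidden_dims=(16, 8, 16))
    out = noise_sweep(src, tgt, etas=(0, 10), config=cfg, seed=0)
    assert set(out) == {0, 10}
    from dadpc.trainer import fit, predict

    model, _, _ = fit(src, tgt, cfg)
    pred, _ = predict(model, tgt.X)
    assert out[0] == pytest.approx(100.0 * (pred == tgt.y).mean())
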