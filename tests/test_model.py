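import numpy as np
import pandas as pd
import pytest
from autograd.misc.flatten import flatten

from scdfn import SCDFN, ParameterError, TrainConfig, joint_loss
from scdfn.metrics import ari

from conftest import fast_config


def build_model(sim, k=3, **cfg_overrides):
    return SCDFN.from_raw_counts(sim.counts, k, knn_k=10,
                                 config=fast_config(**cfg_overrides))


class TestJointLoss:
    def test_single_component(self):
        assert joint_loss(3.5, 9.9, 1.1, 7.7, (1, 0, 0, 0)) == 3.5

    def test_weighted_sum_arithmetic(self):
        assert joint_loss(1, 2, 3, 4, (1, 1, 1, 1)) == 10

    def test_removing_component_equals_zero_weight(self, rng):
        comps = rng.random(4)
        gammas = (0.5, 1.5, 2.0, 0.1)
        dropped = joint_loss(comps[0], comps[1], 0.0, comps[3], gammas)
        zeroed = joint_loss(*comps, (0.5, 1.5, 0.0, 0.1))
        np.testing.assert_allclose(dropped, zeroed)


class TestConfigValidation:
    def test_both_branches_off_rejected(self):
        from scdfn import ConfigurationError

        with pytest.raises(ConfigurationError):
            TrainConfig(use_ae=False, use_igae=False)

    def test_negative_gamma_rejected(self):
        from scdfn import ConfigurationError

        with pytest.raises(ConfigurationError):
            TrainConfig(gammas=(1, -1, 1, 1))

    def test_k_one_rejected(self, small_sim):
        with pytest.raises(ParameterError):
            SCDFN.from_raw_counts(small_sim.counts, 1)


class TestPretrain:
    def test_zero_epochs_leaves_params_unchanged(self, small_sim):
        model = build_model(small_sim, epochs_pretrain=0, epochs_joint=0)
        params = model._init_params(seed=0)
        before, _ = flatten(params)
        out = model.pretrain({k: v for k, v in params.items()}, [])
        after, _ = flatten(out)
        np.testing.assert_array_equal(before, after)

    def test_ae_pretraining_loss_mostly_decreases(self, small_sim):
        # non-increase in at least 8 of the first 10 epochs at lr 1e-3
        model = build_model(small_sim, epochs_pretrain=10, epochs_joint=0,
                            epochs_finetune=0, use_igae=False, use_zinb=False,
                            use_kl=False)
        history = []
        params = model._init_params(seed=0)
        model.pretrain(params, history)
        losses = [h["l_ae"] for h in history if h["phase"] == "pretrain_ae"]
        diffs = np.diff(losses)
        assert (diffs <= 1e-9).sum() >= 8 - 1  # 10 epochs -> 9 diffs


class TestFit:
    def test_deterministic_loss_history_and_labels(self, small_sim):
        r1 = build_model(small_sim).fit(seed=3)
        r2 = build_model(small_sim).fit(seed=3)
        pd.testing.assert_frame_equal(r1.loss_history, r2.loss_history)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_loss_accounting(self, small_sim):
        res = build_model(small_sim).fit(seed=0)
        h = res.loss_history
        expected = [
            joint_loss(r.l_ae, r.l_igae, r.l_kl, r.l_zinb, res.config.gammas)
            for r in h.itertuples()
        ]
        np.testing.assert_allclose(h["total"], expected, rtol=1e-12)

    def test_history_length_counts_executed_epochs(self, small_sim):
        cfg = dict(epochs_pretrain=4, epochs_joint=2, epochs_finetune=5,
                   min_epochs_finetune=5)
        res = build_model(small_sim, **cfg).fit(seed=0)
        assert len(res.loss_history) <= 4 + 4 + 2 + 5
        phases = res.loss_history["phase"].value_counts()
        assert phases["pretrain_ae"] == 4
        assert phases["pretrain_igae"] == 4
        assert phases["pretrain_joint"] == 2

    def test_labels_within_range_and_stable(self, small_sim):
        res = build_model(small_sim).fit(seed=1)
        labels = res.predict()
        assert labels.min() >= 0 and labels.max() < 3
        np.testing.assert_array_equal(labels, res.predict())

    def test_no_empty_cluster_on_separated_fixture(self, small_sim):
        res = build_model(small_sim).fit(seed=1)
        assert len(np.bincount(res.labels, minlength=3).nonzero()[0]) == 3

    def test_recovers_separated_clusters(self, small_sim):
        res = build_model(small_sim).fit(seed=0)
        assert ari(small_sim.true_labels, res.labels) >= 0.9

    def test_null_separation_gives_no_structure(self):
        from scdfn.simulate import SimConfig, simulate

        sim = simulate(SimConfig(n_cells=80, n_genes=100, k_clusters=3,
                                 logfc_scale=0.0, seed=17))
        res = build_model(sim).fit(seed=0)
        assert abs(ari(sim.true_labels, res.labels)) < 0.2

    @pytest.mark.parametrize("ablation", [
        dict(use_ae=False, fuse=False),
        dict(use_igae=False, fuse=False),
        dict(use_kl=False),
        dict(use_zinb=False),
        dict(fuse=False),
    ])
    def test_ablation_variants_run(self, small_sim, ablation):
        res = build_model(small_sim, **ablation).fit(seed=0)
        assert res.labels.shape == (80,)
        assert np.isfinite(res.loss_history["total"]).all()

    def test_summary_and_exports(self, small_sim, tmp_path):
        res = build_model(small_sim).fit(seed=0)
        text = res.summary()
        assert "clusters (k)          3" in text
        res.save_labels(str(tmp_path / "labels.tsv"))
        res.save_embedding(str(tmp_path / "emb.tsv"))
        saved = pd.read_csv(tmp_path / "labels.tsv", sep="\t")
        np.testing.assert_array_equal(saved["cluster"], res.labels)
        emb = pd.read_csv(tmp_path / "emb.tsv", sep="\t", header=None,
                          index_col=0)
        assert emb.shape == res.embedding.shape

    def test_evaluate_shortcut(self, small_sim):
        res = build_model(small_sim).fit(seed=0)
        report = res.evaluate(small_sim.true_labels)
        assert 0 <= report.nmi <= 1 and -1 <= report.ari <= 1

    def test_from_dataframe_constructor(self, small_sim):
        df = small_sim.counts.to_dataframe()
        model = SCDFN.from_dataframe(df, 3, knn_k=10, config=fast_config())
        res = model.fit(seed=0)
        assert res.labels.shape == (80,)

    def test_label_change_logged_during_finetune(self, small_sim):
        res = build_model(small_sim).fit(seed=0)
        ft = res.loss_history[res.loss_history["phase"] == "finetune"]
        assert ft["label_change"].notna().any()
        assert (ft["label_change"].dropna() >= 0).all()

    def test_weight_checkpoint_roundtrip(self, small_sim, tmp_path):
        model = build_model(small_sim)
        res = model.fit(seed=2)
        path = str(tmp_path / "weights.npz")
        model.save_weights(path)
        model2 = build_model(small_sim)
        model2.load_weights(path)
        z1 = model._numpy_embedding(model.params_, train_fusion=True)
        z2 = model2._numpy_embedding(model2.params_, train_fusion=True)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        np.testing.assert_allclose(np.asarray(model2.params_["centers"]),
                                   res.centers, atol=1e-12)

    def test_checkpoint_version_enforced(self, tmp_path):
        from scdfn import ConfigurationError
        from scdfn.networks import load_weights

        bad = str(tmp_path / "bad.npz")
        np.savez(bad, foo=np.ones(3))
        with pytest.raises(ConfigurationError):
            load_weights(bad)

    def test_alpha_beta_reported(self, small_sim):
        res = build_model(small_sim).fit(seed=0)
        assert 0 < res.alpha_final < 1
        assert np.isfinite(res.beta_final)
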