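"""GCN propagation oracles, gradients, and the Model/Results interface."""

import numpy as np
import pytest

import eeggcn as e
from eeggcn import nn
from eeggcn.model import ArchitectureConfig, EEGGraphClassifier, TrainConfig


from _oracles import loop_forward, loop_gcn, random_instance


def small_arch(**kw):
    base = dict(n_nodes=4, m_features=5, gcn_hidden=3, gcn_out=2, n_bands=2,
                fc_hidden=6, fc_hidden2=4, n_classes=2)
    base.update(kw)
    return ArchitectureConfig(**base)


class TestGCNLayer:
    def test_identity_propagation(self, rng):
        x = np.abs(rng.standard_normal((4, 3)))
        out = nn.gcn_layer(x, np.eye(4), np.eye(3))
        np.testing.assert_allclose(out, x)

    def test_matches_per_node_loop_oracle(self, rng):
        x = rng.standard_normal((4, 5))
        a = np.abs(rng.standard_normal((4, 4)))
        a = (a + a.T) / 2
        w = rng.standard_normal((5, 3))
        np.testing.assert_allclose(nn.gcn_layer(x, a, w), loop_gcn(x, a, w),
                                   atol=1e-10)

    def test_zero_input_gives_zero_output(self, rng):
        out = nn.gcn_layer(np.zeros((3, 4)), np.eye(3),
                           rng.standard_normal((4, 2)))
        assert np.all(out == 0.0)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            nn.gcn_layer(np.ones((3, 4)), np.eye(2), np.ones((4, 2)))


class TestForward:
    @pytest.mark.parametrize("n_nodes", [3, 4])
    def test_matches_brute_force_composition(self, n_nodes, rng):
        arch = small_arch(n_nodes=n_nodes)
        params = nn.init_params(arch, rng)
        x, a1, a2 = random_instance(arch, 3, rng)
        logits, _ = nn.forward(params, x, a1, a2)
        for b in range(3):
            np.testing.assert_allclose(
                logits[b], loop_forward(params, x[b], a1[b], a2), atol=1e-8
            )

    def test_probabilities_sum_to_one(self, rng):
        arch = small_arch()
        params = nn.init_params(arch, rng)
        x, a1, a2 = random_instance(arch, 5, rng)
        _, probs = nn.forward(params, x, a1, a2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_channel_permutation_equivariance(self, rng):
        """Permuting channels in X, A1, A2 and the flatten rows of U1
        accordingly leaves the scores unchanged."""
        arch = small_arch()
        params = nn.init_params(arch, rng)
        x, a1, a2 = random_instance(arch, 2, rng)
        perm = rng.permutation(arch.n_nodes)
        xp = x[:, :, perm, :]
        a1p = a1[:, :, perm][:, :, :, perm]
        a2p = a2[perm][:, perm]
        n, l, j = arch.n_nodes, arch.gcn_out, arch.n_bands
        row_map = np.concatenate(
            [jj * n * l + np.repeat(perm, l) * l + np.tile(np.arange(l), n)
             for jj in range(j)]
        )
        pp = dict(params)
        pp["U1"] = params["U1"][row_map]
        logits, _ = nn.forward(params, x, a1, a2)
        logits_p, _ = nn.forward(pp, xp, a1p, a2p)
        np.testing.assert_allclose(logits_p, logits, atol=1e-10)

    def test_zeroed_band_contributes_only_through_its_block(self, rng):
        """Zeroing band 0's features+weights equals zeroing its flatten rows."""
        arch = small_arch()
        params = nn.init_params(arch, rng)
        x, a1, a2 = random_instance(arch, 2, rng)
        xz = x.copy()
        xz[:, 0] = 0.0
        pz = dict(params)
        pz["W0"] = params["W0"].copy()
        pz["W0"][0] = 0.0
        block = arch.n_nodes * arch.gcn_out
        pu = dict(params)
        pu["U1"] = params["U1"].copy()
        pu["U1"][:block] = 0.0
        la, _ = nn.forward(pz, xz, a1, a2)
        lb, _ = nn.forward(pu, x, a1, a2)
        np.testing.assert_allclose(la, lb, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("gcn_bias,sharing", [(False, "per_band"),
                                                  (True, "per_band"),
                                                  (False, "shared")])
    def test_backprop_matches_finite_differences(self, gcn_bias, sharing, rng):
        arch = small_arch(gcn_bias=gcn_bias, weight_sharing=sharing)
        params = nn.init_params(arch, rng)
        x, a1, a2 = random_instance(arch, 3, rng)
        y = np.array([0, 1, 1])
        _, grads = nn.loss_and_grads(params, x, a1, a2, y)
        eps = 1e-6
        for key, g in grads.items():
            flat = params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = nn.loss_and_grads(params, x, a1, a2, y)
                flat[idx] = orig - eps
                lm, _ = nn.loss_and_grads(params, x, a1, a2, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(num, abs=2e-5), key


def test_parameter_count_matches_shape_arithmetic():
    arch = ArchitectureConfig()  # defaults: per-band, no GCN bias
    params = nn.init_params(arch, np.random.default_rng(0))
    j, m, k, l = 5, 32, 16, 2
    n, s, f, z = 19, 128, 32, 2
    expected = j * m * k + j * k * l + (n * l * j * s + s) + (s * f + f) + (f * z + z)
    assert nn.count_parameters(params) == expected == 31362


def test_doubling_k_changes_only_gcn_terms():
    count = {}
    for k in (16, 32):
        arch = ArchitectureConfig(gcn_hidden=k)
        count[k] = nn.count_parameters(nn.init_params(arch, np.random.default_rng(0)))
    assert count[32] - count[16] == 5 * 32 * 16 + 5 * 16 * 2


def test_shared_weights_shrink_the_gcn_block():
    a = nn.count_parameters(
        nn.init_params(ArchitectureConfig(), np.random.default_rng(0)))
    b = nn.count_parameters(
        nn.init_params(ArchitectureConfig(weight_sharing="shared"),
                       np.random.default_rng(0)))
    assert a - b == 4 * (32 * 16 + 16 * 2)


class TestModelFit:
    def _split(self, ds, seed=0):
        plan = e.subject_split(ds, 0.34, seed=seed)
        return plan.apply(ds)

    def test_zero_learning_rate_leaves_parameters_at_init(self, tiny_ds):
        tr, te = self._split(tiny_ds)
        model = EEGGraphClassifier(tr, te)
        tc = TrainConfig(learning_rate=0.0, epochs=4, seed=5)
        res = model.fit(tc)
        init = nn.init_params(model.arch, np.random.default_rng(5))
        for key in init:
            np.testing.assert_array_equal(res.params[key], init[key])
        losses = res.loss_curves["train_loss"].to_numpy()
        np.testing.assert_allclose(losses, losses[0], atol=1e-12)

    def test_identical_seeds_reproduce_the_fit_exactly(self, tiny_ds):
        tr, te = self._split(tiny_ds)
        tc = TrainConfig(epochs=6, seed=9)
        r1 = EEGGraphClassifier(tr, te).fit(tc)
        r2 = EEGGraphClassifier(tr, te).fit(tc)
        for key in r1.params:
            np.testing.assert_array_equal(r1.params[key], r2.params[key])
        assert str(r1.evaluate(te)) == str(r2.evaluate(te))

    def test_learns_the_planted_contrast(self, tiny_ds):
        tr, te = self._split(tiny_ds)
        res = EEGGraphClassifier(tr, te).fit(TrainConfig(epochs=40, seed=0))
        rep = res.evaluate(te)
        assert rep.accuracy >= 90.0

    def test_summary_reports_dimensions_and_count(self, tiny_ds):
        tr, te = self._split(tiny_ds)
        res = EEGGraphClassifier(tr, te).fit(TrainConfig(epochs=2, seed=0))
        text = res.summary()
        assert f"{res.n_parameters:,}" in text
        assert "epochs" in text or "epoch" in text

    def test_single_class_training_split_raises(self, tiny_ds):
        ad_only = tiny_ds.select_subjects(
            [s for s in tiny_ds.subjects if s.startswith("sub-AD")])
        with pytest.raises(ValueError, match="single class"):
            EEGGraphClassifier(ad_only)

    def test_band_order_mismatch_is_rejected_at_predict(self, tiny_ds):
        tr, te = self._split(tiny_ds)
        res = EEGGraphClassifier(tr, te).fit(TrainConfig(epochs=2, seed=0))
        with pytest.raises(ValueError, match="band order|channel set"):
            res.predict_proba(te.subset_bands(["alpha"]))
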