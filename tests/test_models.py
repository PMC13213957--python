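"""EGCL trunk, model heads, pooling, parameter counting and initialization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from carbsite.graph import DegenerateGraphError, build_residue_graph
from carbsite.models import (
    Capsif2,
    ModelConfig,
    PiCAP,
    count_parameters,
    egcl_forward,
    load_checkpoint,
    save_checkpoint,
)
from carbsite.nn import adaptive_pool, init_weights
from carbsite.synthetic import featurize


@pytest.fixture(scope="module")
def tiny_graph(toy_binder, stub_embedder, tiny_config):
    ks = tuple(sorted(set(tiny_config.picap_k_schedule) | {tiny_config.capsif2_k}))
    return featurize(toy_binder, stub_embedder, k_values=ks, with_signal=False)


class TestEgcl:
    def make_inputs(self, seed=0, n=9, k=3, d=8, e=23):
        rng = np.random.default_rng(seed)
        h = rng.standard_normal((n, d))
        nbr = np.stack([rng.permutation(n - 1)[:k] for _ in range(n)])
        nbr = np.where(nbr >= np.arange(n)[:, None], nbr + 1, nbr)  # no self loops
        ef = rng.standard_normal((n, k, e))
        cfg = ModelConfig(n_layers=1, embed_dim=d, input_dim=d, msg_hidden=6,
                          upd_hidden=6, picap_k_schedule=(k,))
        params = Capsif2(cfg, seed=1).params
        return h, nbr, ef, params

    def test_residual_identity_when_update_zeroed(self):
        h, nbr, ef, params = self.make_inputs()
        params["l0_upd2_W"] = np.zeros_like(params["l0_upd2_W"])
        params["l0_upd2_b"] = np.zeros_like(params["l0_upd2_b"])
        out = egcl_forward(h, nbr, ef, params, 0)
        assert np.array_equal(out, h)

    def test_permutation_compatibility(self):
        h, nbr, ef, params = self.make_inputs(seed=2)
        out = egcl_forward(h, nbr, ef, params, 0)
        perm = np.random.default_rng(5).permutation(len(h))
        inv = np.argsort(perm)
        out_p = egcl_forward(h[perm], inv[nbr][perm], ef[perm], params, 0)
        assert np.allclose(out_p, out[perm], atol=1e-12)

    def test_identical_inputs_identical_rows(self):
        h, nbr, ef, params = self.make_inputs(seed=3)
        h[1] = h[0]
        nbr[1] = nbr[0]
        ef[1] = ef[0]
        out = egcl_forward(h, nbr, ef, params, 0)
        assert np.allclose(out[0], out[1], atol=1e-14)


class TestHeads:
    def test_capsif2_output_range_and_determinism(self, tiny_graph, tiny_config):
        m = Capsif2(tiny_config, seed=0)
        p1 = m.forward(tiny_graph)
        p2 = m.forward(tiny_graph)
        assert p1.shape == (tiny_graph.n_nodes,)
        assert np.all((p1 > 0) & (p1 < 1))
        assert np.array_equal(p1, p2)

    def test_picap_output_scalar_any_length(self, stub_embedder, tiny_config, toy_spec):
        from carbsite.synthetic import SyntheticSpec, generate_toy_protein

        m = PiCAP(tiny_config, seed=0)
        for spec in (
            SyntheticSpec(n_proteins=1, length_range=(40, 40), seed=1),
            SyntheticSpec(n_proteins=1, length_range=(400, 400), seed=2),
        ):
            lp = generate_toy_protein(spec, 0)
            g = featurize(lp, stub_embedder, k_values=m.required_k())
            out = float(m.forward(g))
            assert 0.0 < out < 1.0

    def test_rigid_motion_invariance_of_both_heads(self, toy_binder, stub_embedder, tiny_config):
        ks = tuple(sorted(set(tiny_config.picap_k_schedule) | {16}))
        g = featurize(toy_binder, stub_embedder, k_values=ks)
        mc, mp = Capsif2(tiny_config, seed=0), PiCAP(tiny_config, seed=0)
        base_r = mc.forward(g)
        base_p = float(mp.forward(g))
        R = Rotation.random(random_state=8).as_matrix()
        moved = g.coords @ R.T + np.array([12.0, -7.0, 3.0])
        g2 = build_residue_graph(moved, g.node_feats, k_values=ks)
        assert np.allclose(mc.forward(g2), base_r, rtol=1e-5, atol=1e-8)
        assert float(mp.forward(g2)) == pytest.approx(base_p, rel=1e-5)

    def test_degenerate_graph_rejected(self, tiny_config):
        m = Capsif2(tiny_config, seed=0)
        from carbsite.graph import ResidueGraph

        tiny = ResidueGraph(coords=np.zeros((1, 3)), node_feats=np.zeros((1, 32)))
        with pytest.raises(DegenerateGraphError):
            m.forward(tiny)


class TestAdaptivePool:
    @pytest.mark.parametrize("L", [1, 75, 149, 150, 151, 300])
    def test_window_formula_oracle(self, L):
        rng = np.random.default_rng(L)
        x = rng.standard_normal((L, 4))
        out = np.asarray(adaptive_pool(x, 150))
        assert out.shape == (150, 4)
        for t in range(150):
            start = (t * L) // 150
            end = -((-(t + 1) * L) // 150)
            assert np.allclose(out[t], x[start:end].mean(axis=0), atol=1e-12)

    def test_identity_at_target_length(self):
        x = np.random.default_rng(0).standard_normal((150, 3))
        assert np.array_equal(np.asarray(adaptive_pool(x, 150)), x)

    def test_expansion_duplicates_rows(self):
        x = np.arange(75, dtype=float)[:, None]
        out = np.asarray(adaptive_pool(x, 150))
        counts = {v: int((out[:, 0] == v).sum()) for v in x[:, 0]}
        assert all(c == 2 for c in counts.values())


class TestParameterAccounting:
    def test_single_dense_layer_count(self):
        params = init_weights({"W": (128, 1), "b": (1,)}, seed=0)
        assert count_parameters(params) == 129

    def test_counts_depend_only_on_config(self, tiny_config, toy_binder, stub_embedder):
        m = Capsif2(tiny_config, seed=0)
        n0 = m.count_parameters()
        g = featurize(toy_binder, stub_embedder, k_values=(16,))
        m.forward(g)
        assert m.count_parameters() == n0

    def test_default_configs_reproduce_reference_totals(self):
        assert Capsif2(ModelConfig()).count_parameters() == 1_600_387
        assert PiCAP(ModelConfig()).count_parameters() == 1_798_895


class TestInit:
    def test_seeded_reproducibility_and_spread(self):
        shapes = {"a": (200, 250), "b": (100,)}
        w1 = init_weights(shapes, seed=3, sigma=0.02)
        w2 = init_weights(shapes, seed=3, sigma=0.02)
        w3 = init_weights(shapes, seed=4, sigma=0.02)
        assert all(np.array_equal(w1[k], w2[k]) for k in shapes)
        assert not np.array_equal(w1["a"], w3["a"])
        flat = np.concatenate([w1[k].ravel() for k in shapes])
        assert flat.std() == pytest.approx(0.02, rel=0.05)
        assert abs(flat.mean()) < 0.001

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            init_weights({"a": (2, 2)}, seed=0, sigma=0.0)


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, tiny_config, tiny_graph):
        m = Capsif2(tiny_config, seed=5)
        out = m.forward(tiny_graph)
        path = save_checkpoint(m, tmp_path / "m.npz", history={"note": "test"})
        m2 = load_checkpoint(path)
        assert type(m2) is Capsif2
        assert np.array_equal(m2.forward(tiny_graph), out)
        assert m2.history == {"note": "test"}

    def test_transplant_requires_matching_trunk(self, tiny_config):
        donor = Capsif2(tiny_config, seed=0)
        recipient = PiCAP(tiny_config, seed=1)
        head_before = recipient.params["fc1_W"].copy()
        recipient.transplant_trunk(donor.params)
        assert np.array_equal(recipient.params["proj_W"], donor.params["proj_W"])
        assert np.array_equal(recipient.params["fc1_W"], head_before)
        other = Capsif2(
            ModelConfig(n_layers=4, embed_dim=8, input_dim=32, msg_hidden=8,
                        upd_hidden=8, picap_k_schedule=(10, 20, 40, 60)),
            seed=0,
        )
        with pytest.raises(ValueError, match="proj_W"):
            recipient.transplant_trunk(other.params)
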