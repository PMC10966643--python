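"""Readout: breakdown conservation, pair features, invariance, locality."""

from dataclasses import replace

import numpy as np
import pytest

from affinet.egnn import EncoderParams, ModelConfig, encode
from affinet.graphs import build_graphs
from affinet.io_structures import LIGAND, PROTEIN, AtomicComplex, InputError
from affinet.readout import (
    ReadoutParams,
    atomic_readout,
    collate,
    forward_collated,
    pair_feature_vector,
    predict,
)
from affinet.synthetic import make_complex

from conftest import random_rigid_motion


class TestAtomicReadout:
    def test_zero_initialized_outputs_zero(self, small_cfg):
        rng = np.random.default_rng(0)
        enc = EncoderParams(small_cfg, rng)
        ro = ReadoutParams(small_cfg, rng, shift=0.0)
        cx = make_complex(0, 4, seed=0)
        st = encode(build_graphs(cx), cx, enc)
        out = atomic_readout(st, ro)
        assert np.all(out.data == 0.0)

    def test_c_l_scales_linearly(self, small_cfg, small_model):
        enc, ro = small_model
        cx = make_complex(0, 4, seed=1)
        st = encode(build_graphs(cx), cx, enc)
        base = atomic_readout(st, ro).data.copy()
        doubled_cfg = replace(small_cfg, c_L=small_cfg.c_L * 2)
        ro.cfg = doubled_cfg
        try:
            assert np.allclose(atomic_readout(st, ro).data, 2 * base, atol=1e-12)
        finally:
            ro.cfg = small_cfg

    def test_invariant_under_rotation(self, small_model):
        enc, ro = small_model
        cx = make_complex(0, 5, seed=2)
        st = encode(build_graphs(cx), cx, enc)
        base = atomic_readout(st, ro).data.copy()
        rot, trans = random_rigid_motion(np.random.default_rng(9))
        cx2 = replace(cx, coords=cx.coords @ rot.T + trans)
        st2 = encode(build_graphs(cx2), cx2, enc)
        assert np.abs(atomic_readout(st2, ro).data - base).max() <= 1e-5


class TestPairFeatureVector:
    def test_declared_length(self):
        cfg = ModelConfig(n_s=8, n_f=4, n_rbf=8)
        rng = np.random.default_rng(0)
        vec = pair_feature_vector(
            rng.normal(size=8), rng.normal(size=8),
            rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), 2.5, cfg,
        )
        assert vec.shape == (2 * 8 + 8 + 3 * 4 + 4,)  # == 40

    def test_cosine_consistent_with_dot(self):
        cfg = ModelConfig(n_s=4, n_f=3, n_rbf=8)
        rng = np.random.default_rng(1)
        v_i, v_j = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        vec = pair_feature_vector(
            rng.normal(size=4), rng.normal(size=4), v_i, v_j, 3.0, cfg
        )
        n_s, n_f, n_rbf = 4, 3, 8
        off = 2 * n_s + n_rbf
        ni, nj = vec[off : off + n_f], vec[off + n_f : off + 2 * n_f]
        dots = vec[off + 2 * n_f : off + 3 * n_f]
        cos = vec[off + 3 * n_f :]
        assert np.allclose(dots, cos * ni * nj, atol=1e-6)

    def test_zero_norm_cosine_is_zero(self):
        cfg = ModelConfig(n_s=2, n_f=2, n_rbf=8)
        vec = pair_feature_vector(
            np.ones(2), np.ones(2), np.zeros((2, 3)), np.ones((2, 3)), 2.0, cfg
        )
        assert np.allclose(vec[-2:], 0.0, atol=1e-9)

    def test_asymmetric_in_i_and_j(self):
        # ligand block first; swapping roles changes the vector
        cfg = ModelConfig(n_s=4, n_f=2, n_rbf=8)
        rng = np.random.default_rng(2)
        h_i, h_j = rng.normal(size=4), rng.normal(size=4)
        v_i, v_j = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        a = pair_feature_vector(h_i, h_j, v_i, v_j, 2.0, cfg)
        b = pair_feature_vector(h_j, h_i, v_j, v_i, 2.0, cfg)
        assert not np.allclose(a, b)

    def test_all_pairs_cosine_flag(self):
        cfg = ModelConfig(n_s=4, n_f=3, n_rbf=8, pair_cos_all_pairs=True)
        rng = np.random.default_rng(3)
        vec = pair_feature_vector(
            rng.normal(size=4), rng.normal(size=4),
            rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), 2.0, cfg,
        )
        assert vec.shape == (2 * 4 + 8 + 3 * 3 + 9,)
        assert cfg.pair_feature_size == vec.shape[0]


class TestPredict:
    def test_fresh_model_predicts_label_mean(self, small_cfg):
        rng = np.random.default_rng(0)
        enc = EncoderParams(small_cfg, rng)
        shift = float(np.mean([5.0, 6.0, 7.0]))
        ro = ReadoutParams(small_cfg, rng, shift=shift)
        cx = make_complex(12, 5, seed=0)
        bd = predict(cx, build_graphs(cx), enc, ro)
        assert bd.total == 6.0  # exact: readout outputs are zero-initialized

    def test_breakdown_conservation(self, small_model):
        enc, ro = small_model
        cx = make_complex(12, 5, seed=1)
        bd = predict(cx, build_graphs(cx), enc, ro)
        recomposed = bd.shift + bd.atom_contribs.sum() + bd.pair_contribs.sum()
        assert bd.total == pytest.approx(recomposed, abs=1e-6)
        assert len(bd.pair_contribs) > 0

    def test_distant_ligand_reduces_to_atomic_sum(self, small_model):
        enc, ro = small_model
        cx = make_complex(10, 4, seed=2)
        far = replace(
            cx,
            coords=np.where(
                (cx.membership == LIGAND)[:, None], cx.coords + 100.0, cx.coords
            ),
        )
        bd = predict(far, build_graphs(far), enc, ro)
        assert len(bd.pair_contribs) == 0
        assert bd.total == pytest.approx(bd.shift + bd.atom_contribs.sum(), abs=1e-9)

    def test_rigid_motion_invariance_of_total(self, small_model):
        enc, ro = small_model
        cx = make_complex(12, 5, seed=3)
        bd = predict(cx, build_graphs(cx), enc, ro)
        rot, trans = random_rigid_motion(np.random.default_rng(4))
        cx2 = replace(cx, coords=cx.coords @ rot.T + trans)
        bd2 = predict(cx2, build_graphs(cx2), enc, ro)
        assert bd2.total == pytest.approx(bd.total, abs=1e-5)

    def test_ligand_only_mode_ignores_protein(self, small_model):
        enc, ro = small_model
        cx = make_complex(12, 5, seed=4)
        bd = predict(cx, build_graphs(cx), enc, ro, mode="ligand_only")
        assert len(bd.pair_contribs) == 0
        lig = cx.membership == LIGAND
        alone = AtomicComplex(
            elements=cx.elements[lig], coords=cx.coords[lig], membership=cx.membership[lig]
        )
        bd2 = predict(alone, build_graphs(alone), enc, ro, mode="ligand_only")
        assert bd.total == pytest.approx(bd2.total, abs=1e-12)

    def test_locality_protein_deletion(self, small_model, small_cfg):
        enc, ro = small_model
        cx = make_complex(14, 5, seed=5)
        reach = small_cfg.receptive_field
        lig_xyz = cx.coords[cx.membership == LIGAND]
        extra = np.array([[lig_xyz[:, 0].max() + reach + 5.0, 0.0, 0.0]])
        grown = AtomicComplex(
            elements=np.append(cx.elements, 7),
            coords=np.vstack([cx.coords, extra]),
            membership=np.append(cx.membership, PROTEIN),
        )
        bd = predict(cx, build_graphs(cx), enc, ro)
        bd2 = predict(grown, build_graphs(grown), enc, ro)
        assert abs(bd.total - bd2.total) <= 1e-6

    def test_empty_ligand_rejected(self, small_model):
        enc, ro = small_model
        cx = AtomicComplex(elements=[8], coords=[[0, 0, 0]], membership=[PROTEIN])
        with pytest.raises(InputError):
            predict(cx, build_graphs(cx), enc, ro)

    def test_shift_counted_once_for_duplicated_system(self, small_model):
        # two non-interacting copies in one record: prediction is NOT 2x
        enc, ro = small_model
        cx = make_complex(0, 4, seed=6)
        dup = AtomicComplex(
            elements=np.concatenate([cx.elements, cx.elements]),
            coords=np.vstack([cx.coords, cx.coords + 500.0]),
            membership=np.concatenate([cx.membership, cx.membership]),
        )
        bd1 = predict(cx, build_graphs(cx), enc, ro)
        bd2 = predict(dup, build_graphs(dup), enc, ro)
        atomic1 = bd1.total - bd1.shift
        assert bd2.total == pytest.approx(bd1.shift + 2 * atomic1, abs=1e-9)


class TestBatching:
    def test_batched_forward_matches_single_predictions(self, small_model):
        enc, ro = small_model
        complexes = [make_complex(10, 4, seed=s, id=f"c{s}") for s in range(4)]
        graphs = [build_graphs(cx) for cx in complexes]
        col = collate(complexes, graphs)
        totals, _, _ = forward_collated(col, enc, ro)
        singles = [predict(cx, g, enc, ro).total for cx, g in zip(complexes, graphs)]
        assert np.allclose(totals.data, singles, atol=1e-9)

    def test_batched_ligand_only(self, small_model):
        enc, ro = small_model
        complexes = [make_complex(8, 4, seed=s) for s in range(3)]
        graphs = [build_graphs(cx) for cx in complexes]
        col = collate(complexes, graphs, mode="ligand_only")
        totals, _, _ = forward_collated(col, enc, ro, mode="ligand_only")
        singles = [
            predict(cx, g, enc, ro, mode="ligand_only").total
            for cx, g in zip(complexes, graphs)
        ]
        assert np.allclose(totals.data, singles, atol=1e-9)
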