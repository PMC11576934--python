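import numpy as np
import pytest

from hypoparc.infer_engine import (
    ProbabilityMap,
    aggregate_views,
    class_channels,
    predict_plane,
    segment,
    segment_upsample,
    trilinear_resize,
    unmerge_sagittal,
)
from hypoparc.lut_io import HypoparcError, Volume, conform, merge_lateral_labels, toy_lut
from hypoparc.network import NetworkConfig, build_fcnn
from hypoparc.phantom import generate_phantom, toy_phantom_spec

from conftest import make_volume

TINY = dict(n_classes=7, inner_channels=6, outer_channels=4, stack_thickness=3, n_scales=3)


@pytest.fixture(scope="module")
def toy_net():
    # untrained network with frozen random weights: enough for contracts
    return build_fcnn(NetworkConfig(**TINY), "coronal", seed=5)


@pytest.fixture(scope="module")
def toy_vols():
    t1, t2, lab = generate_phantom(toy_phantom_spec(seed=77, voxel_size=1.6))  # 16^3
    return conform(t1), conform(t2), conform(lab)


class TestPredictPlane:
    def test_simplex_and_determinism(self, toy_net, toy_vols, lut_toy):
        t1, t2, _ = toy_vols
        pm = predict_plane(toy_net, {"T1": t1, "T2": t2}, "coronal", "t1t2", lut_toy)
        pm.check_simplex()
        pm2 = predict_plane(toy_net, {"T1": t1, "T2": t2}, "coronal", "t1t2", lut_toy)
        np.testing.assert_array_equal(pm.data, pm2.data)
        assert pm.data.shape == (7,) + t1.shape

    def test_t1_only_equals_zeroed_t2_weight(self, toy_net, toy_vols, lut_toy):
        t1, t2, _ = toy_vols
        only = predict_plane(toy_net, {"T1": t1}, "coronal", "t1_only", lut_toy)
        old = float(toy_net.fusion.w_t2.value)
        toy_net.fusion.w_t2.value[...] = 0.0
        both = predict_plane(toy_net, {"T1": t1, "T2": t2}, "coronal", "t1t2", lut_toy)
        toy_net.fusion.w_t2.value[...] = old
        np.testing.assert_array_equal(only.data, both.data)

    def test_missing_required_volume_rejected(self, toy_net, toy_vols, lut_toy):
        t1, _, _ = toy_vols
        with pytest.raises(HypoparcError):
            predict_plane(toy_net, {"T1": t1}, "coronal", "t1t2", lut_toy)

    def test_plane_mismatch_rejected(self, toy_net, toy_vols, lut_toy):
        t1, _, _ = toy_vols
        with pytest.raises(HypoparcError):
            predict_plane(toy_net, {"T1": t1}, "axial", "t1_only", lut_toy)


class TestUnmergeSagittal:
    def test_copy_rule(self, lut_toy):
        merged, mapping = merge_lateral_labels(lut_toy)
        data = np.zeros((len(merged) + 1, 2, 2, 2))
        ch = class_channels(merged)
        data[ch[2]] = 0.6  # merged "Nucleus" (pair 2/3)
        data[0] = 0.4
        pm = ProbabilityMap(data, merged, (1.0, 1.0, 1.0))
        out = unmerge_sagittal(pm, mapping, lut_toy)
        full_ch = class_channels(lut_toy)
        assert np.all(out.data[full_ch[2]] == 0.6)
        assert np.all(out.data[full_ch[3]] == 0.6)

    def test_pairless_identity(self, pairless_lut):
        merged, mapping = merge_lateral_labels(pairless_lut)
        data = np.random.default_rng(0).dirichlet(np.ones(3), size=(2, 2, 2))
        data = np.moveaxis(data, -1, 0)
        pm = ProbabilityMap(data, merged, (1.0, 1.0, 1.0))
        out = unmerge_sagittal(pm, mapping, pairless_lut)
        np.testing.assert_array_equal(out.data, data)

    def test_one_hot_roundtrip_restores_partner_support(self, lut_toy):
        merged, mapping = merge_lateral_labels(lut_toy)
        mch = class_channels(merged)
        fch = class_channels(lut_toy)
        for lid in lut_toy.ids():
            data = np.zeros((len(merged) + 1, 1, 1, 1))
            data[mch[mapping[lid]]] = 1.0
            out = unmerge_sagittal(
                ProbabilityMap(data, merged, (1.0,) * 3), mapping, lut_toy
            )
            partner = lut_toy[lid].partner_id
            assert out.data[fch[lid], 0, 0, 0] == 1.0
            if partner is not None:
                assert out.data[fch[partner], 0, 0, 0] == 1.0


class TestAggregateViews:
    @staticmethod
    def _pm(data, lut):
        return ProbabilityMap(data, lut, (1.0, 1.0, 1.0))

    def test_identical_maps_unchanged(self, lut_toy, rng):
        raw = rng.dirichlet(np.ones(7), size=(3, 3, 3))
        data = np.moveaxis(raw, -1, 0)
        maps = {p: self._pm(data.copy(), lut_toy) for p in ("axial", "coronal", "sagittal")}
        out = aggregate_views(maps)
        np.testing.assert_allclose(out.data, data)

    def test_two_views_outvote_one(self, lut_toy):
        a = np.zeros((7, 1, 1, 1)); a[1] = 1.0
        b = np.zeros((7, 1, 1, 1)); b[2] = 1.0
        out = aggregate_views(
            {"axial": self._pm(a, lut_toy), "coronal": self._pm(a.copy(), lut_toy),
             "sagittal": self._pm(b, lut_toy)}
        )
        assert out.data[:, 0, 0, 0].argmax() == 1
        assert out.data[1, 0, 0, 0] == pytest.approx(0.8)

    def test_single_view_weight_passthrough(self, lut_toy, rng):
        data = np.moveaxis(rng.dirichlet(np.ones(7), size=(2, 2, 2)), -1, 0)
        out = aggregate_views(
            {"axial": self._pm(data, lut_toy)}, weights={"axial": 1.0}
        )
        np.testing.assert_allclose(out.data, data)

    def test_shape_mismatch_rejected(self, lut_toy):
        a = np.full((7, 2, 2, 2), 1 / 7)
        b = np.full((7, 2, 2, 3), 1 / 7)
        with pytest.raises(HypoparcError):
            aggregate_views({"axial": self._pm(a, lut_toy), "coronal": self._pm(b, lut_toy)})


class TestSegment:
    def test_labelmap_shape_and_volume_arithmetic(self, toy_net, lut_toy):
        t1, t2, lab = generate_phantom(toy_phantom_spec(seed=12, voxel_size=1.6))
        res = segment(t1, t2, {"coronal": toy_net}, lut_toy)
        assert res.labelmap.shape == conform(t1).shape
        # voxel-count volumes: count * voxel volume
        for lid, vol in res.volumes_mm3.items():
            count = int((res.labelmap.data == lid).sum())
            assert vol == pytest.approx(count * 1.6**3)

    def test_volume_scaling_with_voxel_size(self, lut_toy):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab.flat[:100] = 1
        for vs, expect in ((0.8, 51.2), (1.0, 100.0)):
            v = make_volume(lab, (vs,) * 3, modality="LABEL")
            count = int((v.data == 1).sum())
            assert count * v.voxel_volume_mm3() == pytest.approx(expect, rel=1e-9)

    def test_no_input_rejected(self, toy_net, lut_toy):
        with pytest.raises(HypoparcError):
            segment(None, None, {"coronal": toy_net}, lut_toy)

    def test_mismatched_grids_rejected(self, toy_net, lut_toy, rng):
        a = make_volume(rng.random((16, 16, 16)))
        b = make_volume(rng.random((16, 16, 15)), modality="T2")
        with pytest.raises(HypoparcError):
            segment(a, b, {"coronal": toy_net}, lut_toy)

    def test_t2_only_warns(self, toy_net, lut_toy):
        _, t2, _ = generate_phantom(toy_phantom_spec(seed=12, voxel_size=1.6))
        with pytest.warns(UserWarning, match="lowest-performing"):
            segment(None, t2, {"coronal": toy_net}, lut_toy)

    def test_argmax_ties_break_to_lowest_class(self, lut_toy):
        data = np.full((7, 1, 1, 1), 1.0 / 7.0)
        pm = ProbabilityMap(data, lut_toy, (1.0,) * 3)
        from hypoparc.infer_engine import _labelmap_from_probs

        lm = _labelmap_from_probs(pm, np.eye(4))
        assert lm.data[0, 0, 0] == 0  # background channel wins the tie


class TestUpsamplePath:
    def test_work_res_equal_native_matches_segment(self, toy_net, lut_toy):
        t1, t2, _ = generate_phantom(toy_phantom_spec(seed=4, voxel_size=1.6))
        a = segment(t1, t2, {"coronal": toy_net}, lut_toy)
        b = segment_upsample(t1, t2, {"coronal": toy_net}, lut_toy, work_res=1.6)
        np.testing.assert_array_equal(a.labelmap.data, b.labelmap.data)

    def test_trilinear_upsampling_preserves_simplex(self, rng):
        probs = np.moveaxis(rng.dirichlet(np.ones(5), size=(6, 6, 6)), -1, 0)
        up = trilinear_resize(probs, (9, 9, 9))
        np.testing.assert_allclose(up.sum(axis=0), 1.0, atol=1e-5)

    def test_interior_labels_stable_under_upsampling(self):
        # two-region one-hot map: interior voxels keep their label after
        # trilinear soft-label upsampling + argmax
        probs = np.zeros((2, 8, 8, 8))
        probs[0, :4] = 1.0
        probs[1, 4:] = 1.0
        up = trilinear_resize(probs, (16, 16, 16))
        arg = up.argmax(axis=0)
        assert np.all(arg[:6] == 0)
        assert np.all(arg[10:] == 1)

    def test_upsample_path_runs_and_returns_native_grid(self, toy_net, lut_toy):
        t1, t2, lab = generate_phantom(toy_phantom_spec(seed=4, voxel_size=1.28))  # 20^3
        res = segment_upsample(t1, t2, {"coronal": toy_net}, lut_toy, work_res=1.6)
        assert res.labelmap.shape == conform(t1).shape
        assert res.provenance["work_res"] == 1.6
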