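import math

import numpy as np
import pytest

from arrayfret.colocalization import (
    DEFAULT_BIN_EDGES_UM,
    PlaqueModel,
    colocalize,
    distance_profile,
    distance_to_plaque,
    overlap_fraction,
    segment_plaque,
)
from arrayfret.core_io import ChannelVolume, VoxelGeometry
from arrayfret.exceptions import FormatError, PlaqueAbsentError
from arrayfret.segmentation import SegmentationParams, segment_channel
from arrayfret.synthetic import NoiseConfig, PlaqueConfig, SimConfig, generate_stack


def _square(object_factory, s0, span, r0, c0, size, obj_id=0, role="synaptic_post"):
    voxels = [
        (s, r, c)
        for s in range(s0, s0 + span)
        for r in range(r0, r0 + size)
        for c in range(c0, c0 + size)
    ]
    return object_factory(voxels, role=role, obj_id=obj_id)


class TestOverlapFraction:
    def test_disjoint_zero(self, object_factory):
        a = _square(object_factory, 0, 2, 0, 0, 2, 0)
        b = _square(object_factory, 0, 2, 8, 8, 2, 1)
        assert overlap_fraction(a, b) == 0.0

    def test_superset_one(self, object_factory):
        a = _square(object_factory, 0, 2, 4, 4, 2, 0)
        b = _square(object_factory, 0, 2, 3, 3, 4, 1)
        assert overlap_fraction(a, b) == 1.0

    def test_fraction_arithmetic(self, object_factory):
        # synapse: 40 voxels (2 sections x 20 px), intersection 6
        syn_vox = [(s, r, c) for s in (0, 1) for r in range(4) for c in range(5)]
        partner_vox = [(0, r, c) for r in range(2) for c in range(3)]
        syn = object_factory(syn_vox, obj_id=0)
        partner = object_factory(partner_vox, role="donor", obj_id=1)
        assert overlap_fraction(syn, partner) == pytest.approx(0.15)

    def test_asymmetric_denominator(self, object_factory):
        small = _square(object_factory, 0, 2, 4, 4, 2, 0)
        big = _square(object_factory, 0, 2, 4, 4, 4, 1)
        assert overlap_fraction(small, big) == 1.0
        assert overlap_fraction(big, small) == pytest.approx(8 / 32)


class TestColocalize:
    def test_empty_synapse_list_errors(self, object_factory):
        with pytest.raises(FormatError):
            colocalize([], [_square(object_factory, 0, 2, 0, 0, 2)])

    def test_zero_min_fraction_any_overlap(self, object_factory):
        syn = _square(object_factory, 0, 2, 0, 0, 5, 0)
        partner = object_factory([(0, 0, 0)], role="donor", obj_id=1)
        res = colocalize([syn], [partner], min_fraction=0.0)
        assert res.percent == 100.0

    def test_monotone_in_min_fraction(self, quiet_cfg):
        stack, _ = generate_stack(quiet_cfg.replace(n_synapses=40, frac_coloc=0.4))
        params = SegmentationParams()
        syn = segment_channel(stack, "synaptic", params)
        don = segment_channel(stack, "donor", params)
        percents = [
            colocalize(syn, don, f).percent for f in (0.0, 0.05, 0.1, 0.3, 0.9)
        ]
        assert all(a >= b for a, b in zip(percents, percents[1:]))

    def test_synapse_counted_once(self, object_factory):
        syn = _square(object_factory, 0, 2, 0, 0, 4, 0)
        p1 = _square(object_factory, 0, 2, 0, 0, 2, 1, role="donor")
        p2 = _square(object_factory, 0, 2, 2, 2, 2, 2, role="donor")
        res = colocalize([syn], [p1, p2], min_fraction=0.1)
        assert res.percent == 100.0
        assert len(res.colocalized_ids) == 1

    def test_truth_recovery_single_seed(self, quiet_cfg):
        cfg = quiet_cfg.replace(n_synapses=50, frac_coloc=0.3)
        stack, truth = generate_stack(cfg)
        params = SegmentationParams()
        syn = segment_channel(stack, "synaptic", params)
        don = segment_channel(stack, "donor", params)
        acc = segment_channel(stack, "acceptor", params)
        both = colocalize(syn, don).colocalized_ids & colocalize(syn, acc).colocalized_ids
        recovered = 100.0 * len(both) / len(syn)
        expected = 100.0 * truth.n_coloc / truth.n_synapses
        assert recovered == pytest.approx(expected, abs=1e-9)


@pytest.fixture(scope="module")
def plaque_setup():
    geom = VoxelGeometry(200.0, 70.0)
    cfg = SimConfig(
        seed=4,
        frame_size=(320, 320),
        geometry=geom,
        n_sections=6,
        n_synapses=80,
        synapse_radius_xy=(250.0, 400.0),
        plaque=PlaqueConfig(present=True, radius_um=5.0, halo_puncta=6),
        noise=NoiseConfig.off(),
    )
    stack, truth = generate_stack(cfg)
    return cfg, stack, truth


class TestSegmentPlaque:
    def test_no_signal_absent(self, geom):
        model = segment_plaque(ChannelVolume(np.zeros((3, 32, 32))), geom)
        assert not model.present

    def test_small_speckle_absent(self, geom):
        data = np.zeros((3, 64, 64))
        data[1, 10, 10] = 1000.0
        model = segment_plaque(ChannelVolume(data), geom)
        assert not model.present

    def test_synthetic_plaque_recovered(self, plaque_setup):
        cfg, stack, truth = plaque_setup
        model = segment_plaque(stack.channel("donor"), cfg.geometry)
        assert model.present
        true_area = truth.plaque_core_mask.sum()
        est_area = model.core_mask.sum()
        assert abs(est_area - true_area) / true_area <= 0.15

    def test_halo_puncta_excluded(self, plaque_setup):
        cfg, stack, truth = plaque_setup
        model = segment_plaque(stack.channel("donor"), cfg.geometry)
        for obj in truth.noise_objects:
            if obj.channel_role != "donor":
                continue
            vox = np.array(sorted(obj.voxels))
            assert not model.core_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any()

    def test_edge_nonempty_when_present(self, plaque_setup):
        cfg, stack, _ = plaque_setup
        model = segment_plaque(stack.channel("donor"), cfg.geometry)
        assert model.edge_mask.sum() > 0


class TestDistanceToPlaque:
    def _plaque_single_column(self, shape=(4, 64, 64), col=10):
        core = np.zeros(shape, dtype=bool)
        core[:, :, col] = True
        edge = core.copy()
        return PlaqueModel(present=True, core_mask=core, edge_mask=edge)

    def test_centroid_on_edge_is_zero(self, geom, object_factory):
        plaque = self._plaque_single_column()
        obj = object_factory([(1, 5, 10), (2, 5, 10)])
        assert distance_to_plaque(obj, plaque, geom) == 0.0

    def test_inplane_straight_line(self, geom, object_factory):
        plaque = self._plaque_single_column()
        # centroid 100 px from the edge column at 100 nm/px -> 10 um, same section plane
        voxels = [(s, 5, 110) for s in range(4)]
        obj = object_factory(voxels)
        d = distance_to_plaque(obj, plaque, geom)
        assert d == pytest.approx(10.0, abs=0.01)

    def test_absent_plaque_errors(self, geom, object_factory):
        obj = object_factory([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(PlaqueAbsentError):
            distance_to_plaque(obj, PlaqueModel(present=False), geom)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, geom, object_factory, seed):
        rng = np.random.default_rng(seed)
        shape = (4, 32, 32)
        core = np.zeros(shape, dtype=bool)
        r0, c0 = rng.integers(4, 20, 2)
        core[:, r0 : r0 + 6, c0 : c0 + 6] = True
        import scipy.ndimage as ndi

        edge = core & ~ndi.binary_erosion(core, ndi.generate_binary_structure(3, 1))
        plaque = PlaqueModel(present=True, core_mask=core, edge_mask=edge)
        for _ in range(5):
            s, r, c = rng.integers(0, 4), rng.integers(0, 32), rng.integers(0, 32)
            obj = object_factory([(s, r, c), (min(s + 1, 3), r, c)])
            got = distance_to_plaque(obj, plaque, geom)
            x, y, z = obj.centroid_nm
            sc, rc, cc = round(z / 70), round(y / 100), round(x / 100)
            if core[sc, rc, cc]:
                assert got == 0.0
                continue
            best = math.inf
            for es, er, ec in zip(*np.nonzero(edge)):
                d = math.sqrt(
                    (es * 70 - z) ** 2 + (er * 100 - y) ** 2 + (ec * 100 - x) ** 2
                )
                best = min(best, d / 1000.0)
            assert got == pytest.approx(best, rel=1e-9)


class TestDistanceProfile:
    def test_far_objects_only_reference_bin(self, geom, object_factory):
        shape = (4, 64, 700)
        core = np.zeros(shape, dtype=bool)
        core[:, :, :3] = True
        import scipy.ndimage as ndi

        edge = core & ~ndi.binary_erosion(core, ndi.generate_binary_structure(3, 1))
        plaque = PlaqueModel(present=True, core_mask=core, edge_mask=edge)
        # objects at column 650 -> ~64 um away
        objs = [
            object_factory([(0, r, 650), (1, r, 650)], obj_id=i)
            for i, r in enumerate((10, 30, 50))
        ]
        valid = np.ones(shape, dtype=bool)
        profile = distance_profile(objs, plaque, valid, geom)
        assert profile.counts[-1] == 3
        assert profile.counts[:-1].sum() == 0

    def test_counts_sum_to_total(self, plaque_setup):
        cfg, stack, truth = plaque_setup
        model = segment_plaque(stack.channel("donor"), cfg.geometry)
        objs = truth.objects_by_role("synaptic_post")
        profile = distance_profile(
            objs, model, stack.full_valid_mask(), cfg.geometry
        )
        assert profile.counts.sum() == len(objs)

    def test_empty_bin_density_is_nan(self, geom, object_factory):
        shape = (4, 32, 32)  # frame only ~3 um wide: far bins have no volume
        core = np.zeros(shape, dtype=bool)
        core[:, 14:18, 14:18] = True
        import scipy.ndimage as ndi

        edge = core & ~ndi.binary_erosion(core, ndi.generate_binary_structure(3, 1))
        plaque = PlaqueModel(present=True, core_mask=core, edge_mask=edge)
        profile = distance_profile(
            [], plaque, np.ones(shape, dtype=bool), geom
        )
        assert profile.volumes_mm3[0] > 0
        assert np.isnan(profile.densities[-1])

    def test_truth_profile_recovered_noise_free(self, plaque_setup):
        """Counts match truth up to +/-1 per bin (bin-edge straddling:
        the segmented footprint is slightly larger than the half-max
        truth set, so centroids can shift by a fraction of a pixel)."""
        cfg, stack, truth = plaque_setup
        model = segment_plaque(stack.channel("donor"), cfg.geometry)
        syn = segment_channel(stack, "synaptic", SegmentationParams())
        profile = distance_profile(syn, model, stack.full_valid_mask(), cfg.geometry)
        assert profile.counts.sum() == truth.true_bin_counts.sum()
        assert np.abs(profile.counts - truth.true_bin_counts).max() <= 1

    def test_bin_edges_default(self):
        assert DEFAULT_BIN_EDGES_UM[:6] == (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
        assert math.isinf(DEFAULT_BIN_EDGES_UM[-1])
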