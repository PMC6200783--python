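"""Slab geometry: SCT measurement, slab placement, index resolution and
en-face projection."""

import numpy as np
import pytest

from choroflow import (
    CHORIOCAPILLARIS_SLAB,
    DEVICE_DEFAULT_CC_SLAB,
    OCTAVolume,
    PhantomParams,
    SlabSpec,
    SurfaceMap,
    ThinChoroidWarning,
    extract_slab,
    generate_vessel_network,
    half_choroid_spec,
    measure_sct,
    project_slab,
    render_phantom_volume,
    resolve_slab,
)


def flat_surfaces(shape=(8, 8), rpe=100.0, csi=390.0, fovea=(4, 4)):
    return SurfaceMap(
        rpe_outer_depth_um=np.full(shape, rpe),
        csi_depth_um=np.full(shape, csi),
        fovea_position=fovea,
    )


def make_volume(depth_values, shape=(4, 4), axial_pitch=10.0):
    depth_values = np.asarray(depth_values, dtype=np.uint8)
    flow = np.broadcast_to(depth_values, shape + depth_values.shape).copy()
    return OCTAVolume(flow=flow, axial_pitch_um=axial_pitch, lateral_pitch_um=20.0)


class TestMeasureSct:
    @pytest.mark.parametrize(
        "rpe, csi, expected", [(100.0, 390.0, 290.0), (250.0, 250.0, 0.0), (120.0, 550.0, 430.0)]
    )
    def test_caliper_reads_surface_difference_at_fovea(self, rpe, csi, expected):
        assert measure_sct(flat_surfaces(rpe=rpe, csi=csi)) == expected

    def test_translation_invariance(self, rng):
        rpe = rng.uniform(50, 150, (8, 8))
        csi = rpe + rng.uniform(150, 400, (8, 8))
        s0 = SurfaceMap(rpe, csi, (3, 3))
        s1 = SurfaceMap(rpe + 77.0, csi + 77.0, (3, 3))
        assert measure_sct(s0) == pytest.approx(measure_sct(s1))

    def test_median_window_suppresses_a_spike(self):
        s = flat_surfaces()
        s.csi_depth_um[4, 4] = 900.0  # corrupted fovea A-scan
        assert measure_sct(s) == 800.0
        assert measure_sct(s, window_halfwidth=1) == 290.0

    def test_fovea_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="fovea"):
            flat_surfaces(fovea=(9, 0))

    def test_inverted_surfaces_rejected(self):
        with pytest.raises(ValueError, match="above the outer RPE"):
            SurfaceMap(np.full((4, 4), 300.0), np.full((4, 4), 200.0), (0, 0))


class TestHalfChoroidSpec:
    @pytest.mark.parametrize("sct, offset", [(290.0, 130.0), (500.0, 235.0)])
    def test_window_centered_on_half_thickness(self, sct, offset):
        spec = half_choroid_spec(sct)
        assert spec.offset_um == offset
        assert spec.width_um == 30.0

    def test_start_placement_begins_at_half_thickness(self):
        assert half_choroid_spec(290.0, placement="start").offset_um == 145.0

    def test_degenerate_thickness_rejected(self):
        with pytest.raises(ValueError, match="slab"):
            half_choroid_spec(30.0)

    def test_thin_choroid_warns_below_eligibility_cutoff(self):
        with pytest.warns(ThinChoroidWarning):
            half_choroid_spec(140.0)

    def test_presets(self):
        assert (CHORIOCAPILLARIS_SLAB.offset_um, CHORIOCAPILLARIS_SLAB.width_um) == (30.0, 30.0)
        assert (DEVICE_DEFAULT_CC_SLAB.offset_um, DEVICE_DEFAULT_CC_SLAB.width_um) == (29.0, 20.0)


class TestResolveSlab:
    def test_index_interval_rounds_half_up(self):
        vol = make_volume(np.zeros(40), axial_pitch=10.0)
        surf = flat_surfaces(shape=(4, 4), rpe=100.0, csi=390.0, fovea=(0, 0))
        start, stop = resolve_slab(SlabSpec(offset_um=30.0, width_um=30.0), surf, vol)
        assert np.all(start == 13) and np.all(stop == 16)

    def test_index_interval_finer_pitch(self):
        vol = make_volume(np.zeros(40), axial_pitch=5.0)
        surf = flat_surfaces(shape=(4, 4), rpe=0.0, csi=150.0, fovea=(0, 0))
        start, stop = resolve_slab(SlabSpec(offset_um=30.0, width_um=30.0), surf, vol)
        assert np.all(start == 6) and np.all(stop == 12)

    def test_interval_never_empty_for_thin_slab(self):
        vol = make_volume(np.zeros(40), axial_pitch=10.0)
        surf = flat_surfaces(shape=(4, 4), rpe=100.0, csi=390.0, fovea=(0, 0))
        start, stop = resolve_slab(SlabSpec(offset_um=30.0, width_um=2.0), surf, vol)
        assert np.all(stop - start >= 1)

    def test_start_monotone_in_offset(self, rng):
        vol = make_volume(np.zeros(100), axial_pitch=7.0)
        surf = SurfaceMap(rng.uniform(0, 100, (4, 4)), np.full((4, 4), 700.0), (0, 0))
        offsets = np.sort(rng.uniform(0, 400, 10))
        starts = [resolve_slab(SlabSpec(o, 30.0), surf, vol)[0] for o in offsets]
        for earlier, later in zip(starts, starts[1:]):
            assert np.all(later >= earlier)

    def test_slab_exiting_volume_names_positions(self):
        vol = make_volume(np.zeros(12), axial_pitch=10.0)
        surf = flat_surfaces(shape=(4, 4), rpe=100.0, csi=390.0, fovea=(0, 0))
        with pytest.raises(ValueError, match=r"axial extent.*\(0, 0\)"):
            resolve_slab(SlabSpec(offset_um=30.0, width_um=30.0), surf, vol)


class TestProjectSlab:
    def test_constant_slab_any_rule(self):
        vol = make_volume(np.full(10, 77))
        surf = flat_surfaces(shape=(4, 4), rpe=0.0, csi=90.0, fovea=(0, 0))
        iv = resolve_slab(SlabSpec(0.0, 100.0), surf, vol)
        assert np.all(project_slab(vol, iv, "max").pixels == 77)
        assert np.all(project_slab(vol, iv, "mean").pixels == 77)

    def test_mean_and_max_of_known_depth_profile(self):
        vol = make_volume([10, 20, 30])
        iv = (np.zeros((4, 4), dtype=int), np.full((4, 4), 3, dtype=int))
        assert np.all(project_slab(vol, iv, "mean").pixels == 20)
        assert np.all(project_slab(vol, iv, "max").pixels == 30)

    def test_matches_per_pixel_loop_oracle(self, rng):
        flow = rng.integers(0, 256, (6, 5, 20), dtype=np.uint8)
        vol = OCTAVolume(flow=flow, axial_pitch_um=8.0, lateral_pitch_um=20.0)
        start = rng.integers(0, 10, (6, 5))
        stop = start + rng.integers(1, 10, (6, 5))
        for rule in ("max", "mean"):
            got = project_slab(vol, (start, stop), rule).pixels
            for r in range(6):
                for c in range(5):
                    window = flow[r, c, start[r, c] : stop[r, c]].astype(float)
                    want = window.max() if rule == "max" else np.floor(window.mean() + 0.5)
                    assert got[r, c] == want

    def test_max_dominates_mean_pixelwise(self, rng):
        flow = rng.integers(0, 256, (8, 8, 16), dtype=np.uint8)
        vol = OCTAVolume(flow=flow, axial_pitch_um=8.0, lateral_pitch_um=20.0)
        iv = (np.zeros((8, 8), dtype=int), np.full((8, 8), 16, dtype=int))
        assert np.all(project_slab(vol, iv, "max").pixels >= project_slab(vol, iv, "mean").pixels)

    def test_mismatched_grids_rejected(self):
        vol = make_volume(np.zeros(10))
        with pytest.raises(ValueError, match="lateral grid"):
            project_slab(vol, (np.zeros((3, 3), dtype=int), np.ones((3, 3), dtype=int)))


class TestPhantomVolumeRoundTrip:
    def test_bright_choriocapillaris_layer_recovered_from_volume(self):
        """A phantom with its choriocapillaris layer 30-60 um below the RPE
        yields a slab image whose mean sits within noise of the set value."""
        params = PhantomParams(grid=(64, 64), noise_sd=4.0, seed=3)
        mask = generate_vessel_network(params)
        volume, surfaces = render_phantom_volume(params, mask)
        spec = SlabSpec(offset_um=30.0, width_um=30.0, projection="mean")
        cc = extract_slab(volume, surfaces, spec, "choriocapillaris")
        assert abs(float(cc.pixels.mean()) - params.cc_intensity) < 3 * params.noise_sd
        assert measure_sct(surfaces) == params.sct_um
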