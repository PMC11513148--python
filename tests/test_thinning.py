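"""Thickness maps: leaflet assignment, binning, thinning recovery, frame I/O."""

import numpy as np
import pytest

from qcprof import synthetic as syn
from qcprof import thinning as thin


def _frame(z_upper, z_lower, xy=None, index=0, tags=True):
    n_u, n_l = len(z_upper), len(z_lower)
    if xy is None:
        xy = np.tile([1.0, 1.0], (n_u + n_l, 1))
    z = np.concatenate([z_upper, z_lower])
    leaflet = (
        np.array(["upper"] * n_u + ["lower"] * n_l, dtype="U10")
        if tags
        else np.full(n_u + n_l, "unassigned", dtype="U10")
    )
    return thin.BilayerFrame(index=index, xyz=np.column_stack([xy[:, 0], xy[:, 1], z]),
                             leaflet=leaflet)


# --- leaflet assignment -----------------------------------------------------


def test_flat_sheets_recovered_perfectly():
    xy = np.random.default_rng(0).uniform(0, 10, size=(20, 2))
    f = _frame([20.0] * 10, [-20.0] * 10, xy=xy, tags=False)
    out = thin.assign_leaflets(f)
    assert list(out.leaflet[:10]) == ["upper"] * 10
    assert list(out.leaflet[10:]) == ["lower"] * 10


def test_two_points_per_side():
    f = _frame([10.0, 10.5], [-10.0, -10.5], tags=False)
    out = thin.assign_leaflets(f)
    assert set(out.leaflet) == {"upper", "lower"}


def test_point_at_median_assigned_lower_with_warning():
    # odd count: the median coincides with the three z = 1.0 points
    xyz = np.array([[0, 0, 1.0], [0, 0, 1.0], [0, 0, 1.0], [0, 0, 5.0], [0, 0, -5.0]])
    f = thin.BilayerFrame(0, xyz, np.full(5, "unassigned", dtype="U10"))
    with pytest.warns(UserWarning, match="median"):
        out = thin.assign_leaflets(f)
    assert (out.leaflet == "lower").sum() == 4


def test_one_sided_frame_rejected():
    xyz = np.tile([0.0, 0.0, 7.0], (6, 1))
    f = thin.BilayerFrame(0, xyz, np.full(6, "unassigned", dtype="U10"))
    with pytest.raises(ValueError, match="one-sided"):
        thin.assign_leaflets(f)


def test_noisy_synthetic_tags_fully_recovered():
    """thermal_sd 1, separation 40: median split recovers generator tags."""
    spec = syn.SyntheticBilayerSpec(n_lipids_per_leaflet=500, n_frames=5, seed=13)
    tagged = syn.generate_bilayer_trajectory(spec)
    withheld = syn.generate_bilayer_trajectory(spec, withhold_tags=True)
    for ft, fw in zip(tagged, withheld):
        out = thin.assign_leaflets(fw)
        assert np.array_equal(out.leaflet, ft.leaflet)


# --- thickness map ----------------------------------------------------------


def test_flat_noiseless_map_exact():
    spec = syn.SyntheticBilayerSpec(
        n_lipids_per_leaflet=500, dimple_depth=0.0, thermal_sd=0.0, n_frames=5, seed=0
    )
    frames = syn.generate_bilayer_trajectory(spec)
    tmap = thin.thickness_map(frames, bin_size=5.0, window=(0.0, 1.0))
    vals = tmap.mean[tmap.populated]
    assert np.allclose(vals, 40.0)


def test_single_frame_single_bin_arithmetic():
    f = _frame([21.0, 19.0], [-20.0], xy=np.array([[1, 1], [1, 1], [1, 1]], float))
    tmap = thin.thickness_map([f, f, f, f], bin_size=4.0, window=(0.0, 1.0))
    assert np.nanmax(tmap.mean) == pytest.approx(40.0)


def test_window_selects_trailing_fraction():
    flat = _frame([20.0] * 3, [-20.0] * 3)
    with pytest.raises(ValueError):
        thin.thickness_map([flat], window=(0.5, 0.4))
    tmap = thin.thickness_map([flat] * 10, window=(0.6, 1.0))
    assert tmap.frames_used == 4
    assert tmap.window == (6, 10)


def test_empty_bins_flagged_not_zero():
    f = _frame([20.0], [-20.0], xy=np.array([[1, 1], [1, 1]], float))
    f2 = _frame([20.0], [-20.0], xy=np.array([[9, 9], [9, 9]], float), index=1)
    tmap = thin.thickness_map([f, f2], bin_size=2.0, window=(0.0, 1.0))
    assert np.isnan(tmap.mean[~tmap.populated]).all()
    assert (tmap.count[~tmap.populated] == 0).all()


def test_dimple_map_minimum_recovered(dimple_frames):
    """depth 5, σ 8, sd 1, 100 frames: map minimum within ±0.3 of bulk − 5."""
    spec, frames = dimple_frames
    tmap = thin.thickness_map(frames, bin_size=2.0)
    assert abs(np.nanmin(tmap.mean) - 35.0) <= 0.3


def test_translation_invariance(dimple_frames):
    _, frames = dimple_frames
    sub = frames[-10:]
    shifted = [
        thin.BilayerFrame(f.index, f.xyz + np.array([0.0, 0.0, 7.3]), f.leaflet,
                          f.lipid_id, box_xy=f.box_xy)
        for f in sub
    ]
    a = thin.thickness_map(sub, window=(0.0, 1.0))
    b = thin.thickness_map(shifted, window=(0.0, 1.0))
    assert np.allclose(a.mean, b.mean, equal_nan=True)


def test_frame_order_invariance(dimple_frames):
    _, frames = dimple_frames
    sub = list(frames[-12:])
    a = thin.thickness_map(sub, window=(0.0, 1.0))
    b = thin.thickness_map(sub[::-1], window=(0.0, 1.0))
    assert np.allclose(a.mean, b.mean, equal_nan=True)


# --- thinning summary & difference ------------------------------------------


def test_uniform_map_thinning_zero():
    spec = syn.SyntheticBilayerSpec(
        n_lipids_per_leaflet=300, dimple_depth=0.0, thermal_sd=0.0, n_frames=3, seed=2
    )
    tmap = thin.thickness_map(syn.generate_bilayer_trajectory(spec), bin_size=5.0,
                              window=(0.0, 1.0))
    s = thin.thinning_summary(tmap, bulk_radius=10.0)
    assert s.max_thinning == pytest.approx(0.0, abs=1e-9)


def test_dimple_thinning_five_angstrom(dimple_frames):
    spec, frames = dimple_frames
    s = thin.thinning_summary(thin.thickness_map(frames))
    assert abs(s.max_thinning - 5.0) <= 0.3
    assert np.hypot(s.min_bin[0] - 25.0, s.min_bin[1] - 25.0) <= 4.0


def test_bulk_radius_too_large_rejected(dimple_frames):
    _, frames = dimple_frames
    tmap = thin.thickness_map(frames)
    with pytest.raises(ValueError, match="too small"):
        thin.thinning_summary(tmap, bulk_radius=200.0)


def test_difference_identical_maps_zero(dimple_frames):
    _, frames = dimple_frames
    tmap = thin.thickness_map(frames)
    d = thin.difference_map(tmap, tmap)
    assert np.allclose(d.diff[np.isfinite(d.diff)], 0.0)
    assert d.delta_max_thinning == pytest.approx(0.0)


def test_difference_of_depths_recovers_delta(dimple_frames):
    """depth 5 vs depth 2.5 generators → Δ max-thinning = 2.5 ± 0.4."""
    spec, frames = dimple_frames
    spec_b = syn.SyntheticBilayerSpec(
        box_xy=spec.box_xy, n_lipids_per_leaflet=spec.n_lipids_per_leaflet,
        bulk_separation=spec.bulk_separation, dimple_center=spec.dimple_center,
        dimple_depth=2.5, dimple_sigma=spec.dimple_sigma,
        thermal_sd=spec.thermal_sd, n_frames=spec.n_frames, seed=spec.seed + 1,
    )
    map_a = thin.thickness_map(frames)
    map_b = thin.thickness_map(syn.generate_bilayer_trajectory(spec_b))
    d = thin.difference_map(map_a, map_b)
    assert abs(d.delta_max_thinning - 2.5) <= 0.4
    swapped = thin.difference_map(map_b, map_a)
    assert swapped.delta_max_thinning == pytest.approx(-d.delta_max_thinning)
    both = np.isfinite(d.diff) & np.isfinite(swapped.diff)
    assert np.allclose(d.diff[both], -swapped.diff[both])


def test_dimple_parameter_recovery(dimple_frames):
    """Depth via the summary, σ via the half-depth radius, both within 10%."""
    spec, frames = dimple_frames
    tmap = thin.thickness_map(frames)
    s = thin.thinning_summary(tmap)
    assert abs(s.max_thinning - spec.dimple_depth) / spec.dimple_depth <= 0.10
    # half-depth radius from the area of the above-half-depth region
    # (robust to the empirical minimum sitting a bin or two off-center)
    depth_field = s.bulk_thickness - tmap.mean
    half = (depth_field >= s.max_thinning / 2) & np.isfinite(tmap.mean)
    bin_area = np.diff(tmap.x_edges)[0] * np.diff(tmap.y_edges)[0]
    r_half = np.sqrt(half.sum() * bin_area / np.pi)
    sigma_hat = r_half / np.sqrt(2 * np.log(2))
    assert abs(sigma_hat - spec.dimple_sigma) / spec.dimple_sigma <= 0.10


# --- frame I/O --------------------------------------------------------------


def test_xyz_round_trip(dimple_frames):
    _, frames = dimple_frames
    sub = frames[:2]
    text = thin.write_xyz_frames(sub)
    back = thin.read_xyz_frames(text)
    assert len(back) == 2
    for a, b in zip(sub, back):
        assert np.allclose(a.xyz, b.xyz, atol=1e-4)
        assert np.array_equal(a.leaflet, b.leaflet)
        assert b.box_xy == a.box_xy


def test_pdb_round_trip():
    rng = np.random.default_rng(4)
    xyz = np.round(rng.uniform(-20, 20, size=(8, 3)), 3)
    leaflet = np.array(["upper"] * 4 + ["lower"] * 4, dtype="U10")
    f = thin.BilayerFrame(0, xyz, leaflet)
    back = thin.read_pdb_frames(thin.write_pdb_frames([f, f]))
    assert len(back) == 2
    assert np.allclose(back[0].xyz, xyz, atol=1e-3)
    assert np.array_equal(back[0].leaflet, leaflet)


def test_map_tsv_has_na_for_empty_bins():
    f = _frame([20.0], [-20.0], xy=np.array([[1, 1], [1, 1]], float))
    tmap = thin.thickness_map([f], bin_size=1.0, window=(0.0, 1.0))
    assert "NA" in tmap.to_tsv() or tmap.populated.all()
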