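import numpy as np
import pytest
from scipy import stats

from dtraf import (
    Dendrite,
    DendriteGeometry,
    Spine,
    SynthConfig,
    gen_delivery_course,
    gen_geometry,
    gen_photoconversion,
    gen_spine_field,
    gen_tracks,
    place_puncta,
    render_frame,
)
from dtraf.synthgen import LABEL_DENDRITE, LABEL_SOMA, _points_in_mask


# ---------------------------------------------------------------------- config

def test_config_validates_probabilities_and_positives():
    with pytest.raises(ValueError, match="p_couple"):
        SynthConfig(p_couple=1.5)
    with pytest.raises(ValueError, match="pixel_size_um"):
        SynthConfig(pixel_size_um=0.0)
    with pytest.raises(ValueError):
        SynthConfig(read_noise_sd=-1.0)


# -------------------------------------------------------------------- geometry

def test_geometry_deterministic(small_config):
    g1, m1 = gen_geometry(small_config)
    g2, m2 = gen_geometry(small_config)
    assert np.array_equal(m1.raster, m2.raster)
    assert np.array_equal(g1.dendrites[0].centerline, g2.dendrites[0].centerline)


def test_soma_mask_pixel_count_oracle():
    cfg = SynthConfig()  # soma radius 8 um at 0.1 um pixels
    _geo, mask = gen_geometry(cfg)
    count = int((mask.raster == LABEL_SOMA).sum())
    assert abs(count - np.pi * 80 ** 2) / (np.pi * 80 ** 2) < 0.02


def test_zero_dendrites_gives_soma_only():
    cfg = SynthConfig(n_dendrites=0)
    geo, mask = gen_geometry(cfg)
    assert len(geo.dendrites) == 0
    assert (mask.raster == LABEL_SOMA).any()
    assert not (mask.raster == LABEL_DENDRITE).any()


def test_soma_wins_overlap(small_config, small_field):
    geo, mask = small_field
    # the dendrite starts inside the soma disc; those pixels must be soma
    assert not ((mask.raster == LABEL_DENDRITE)
                & (mask.boolean(LABEL_SOMA))).any()


def test_out_of_bounds_dendrite_named_error():
    cfg = SynthConfig(image_shape=(60, 100), soma_center_um=(3.5, 3.0),
                      soma_radius_um=2.5, dendrite_length_um=60.0)
    with pytest.raises(ValueError, match="dendrite 0"):
        gen_geometry(cfg)


def test_spine_discs_straddle_dendrite_boundary(small_config, small_field):
    geo, mask = small_field
    dend = mask.boolean(LABEL_DENDRITE) | mask.boolean(LABEL_SOMA)
    px = small_config.pixel_size_um
    for sp in geo.spines:
        center = geo.spine_center(sp)
        # center is outside the dendrite mask, but the disc reaches inside
        assert not _points_in_mask(center[None], dend, px)[0]
        den = geo.dendrites[sp.dendrite_index]
        pos, _t, n, hw = den.point_at(sp.arc_pos)
        inner = center - sp.side * sp.radius * n[0]
        assert _points_in_mask(inner[None], dend, px)[0]


def test_dendrite_validation():
    with pytest.raises(ValueError):
        Dendrite(np.array([[0.0, 0.0], [0.0, 0.0]]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        Dendrite(np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        DendriteGeometry((0, 0), -1.0)


# ----------------------------------------------------------------- place_puncta

def test_place_puncta_density_error(small_field):
    geo, mask = small_field
    with pytest.raises(ValueError):
        place_puncta(geo, mask, 0.0)


def test_place_puncta_coupling_requires_partner(small_field):
    geo, mask = small_field
    with pytest.raises(ValueError):
        place_puncta(geo, mask, 0.5, coupling={"p_couple": 0.5})


def test_place_puncta_uncoupled_uniform_and_inside(small_field, small_config):
    geo, mask = small_field
    puncta, truth = place_puncta(geo, mask, 34.0, seed=0)  # ~2000 puncta
    assert not truth.coupled.any()
    cell = (mask.raster == LABEL_SOMA) | (mask.raster == LABEL_DENDRITE)
    assert _points_in_mask(puncta.points, cell, small_config.pixel_size_um).all()
    # chi-square uniformity of x over 10 equal arcs of the dendrite
    den = geo.dendrites[0]
    x0 = den.centerline[0, 0]
    arcs = (puncta.points[:, 0] - x0)
    sel = (arcs >= 0) & (arcs < den.length)
    counts, _ = np.histogram(arcs[sel], bins=10, range=(0.0, den.length))
    p = stats.chisquare(counts).pvalue
    assert p > 0.001


def test_place_puncta_fully_coupled_close_to_partner(small_field):
    geo, mask = small_field
    partner, _ = place_puncta(geo, mask, 1.0, seed=1, channel="a")
    coupled, truth = place_puncta(
        geo, mask, 1.0, coupling={"p_couple": 1.0, "sigma_couple_um": 0.2},
        partner=partner, seed=2, channel="b")
    assert truth.coupled.all()
    from dtraf import min_distances
    d = min_distances(coupled, partner)
    # folded-normal(0.2): P(< 0.5 um) ~ 0.987; allow sampling slack
    assert np.mean(d < 0.5) >= 0.95


def test_place_puncta_poisson_count(small_field):
    geo, mask = small_field
    density = 0.15
    n = len(place_puncta(geo, mask, density, seed=3)[0])
    expect = density * geo.total_centerline_length
    assert abs(n - expect) <= 3 * np.sqrt(expect) + 1


# ----------------------------------------------------------------- render_frame

def test_render_zero_everything(small_field):
    geo, mask = small_field
    cfg = SynthConfig(image_shape=mask.raster.shape, soma_center_um=(3.5, 3.0),
                      soma_radius_um=2.5, background_level=0.0, read_noise_sd=0.0)
    from dtraf.synthgen import PunctaSet
    empty = PunctaSet("c", 0, np.empty((0, 2)), np.empty(0))
    img = render_frame(mask, [empty], cfg, noise=False)
    assert not img.data.any()


def test_render_single_spot_argmax_and_integral(small_field, small_config):
    geo, mask = small_field
    from dtraf.synthgen import PunctaSet
    cfg = SynthConfig(image_shape=mask.raster.shape, soma_center_um=(3.5, 3.0),
                      soma_radius_um=2.5, background_level=0.0)
    point = np.array([[20.05, 3.05]])  # a pixel center on the dendrite
    ps = PunctaSet("c", 0, point, np.array([2000.0]))
    img = render_frame(mask, [ps], cfg, noise=False)
    frame = img.data[0, 0]
    r, c = np.unravel_index(np.argmax(frame), frame.shape)
    px = cfg.pixel_size_um
    assert abs((c + 0.5) * px - 20.05) < px
    assert abs((r + 0.5) * px - 3.05) < px
    # integrated counts within 1% of amplitude * photon_scale
    assert abs(frame.sum() - 2000.0) / 2000.0 < 0.01


def test_render_conservation_multiple_spots(small_field):
    geo, mask = small_field
    from dtraf.synthgen import PunctaSet
    cfg = SynthConfig(image_shape=mask.raster.shape, soma_center_um=(3.5, 3.0),
                      soma_radius_um=2.5, background_level=0.0)
    pts, truth = place_puncta(geo, mask, 0.3, seed=4, amplitude=1500.0)
    img = render_frame(mask, [pts], cfg, noise=False)
    total = img.data.sum()
    assert abs(total - truth.amplitude.sum()) / truth.amplitude.sum() < 0.01


# -------------------------------------------------------------------- gen_tracks

def test_gen_tracks_fdp_bounds(small_field, small_config):
    geo, _ = small_field
    with pytest.raises(ValueError):
        gen_tracks(geo, 5, 1.5, small_config, render=False)
    with pytest.raises(ValueError):
        gen_tracks(geo, 5, 0.5, small_config, n_frames=1, render=False)


def test_gen_tracks_truth_labels_extremes(small_field, small_config):
    geo, _ = small_field
    _t, truth1, _m = gen_tracks(geo, 40, 1.0, small_config, seed=5, render=False)
    cargo1 = truth1[truth1.kind == "cargo"]
    assert cargo1.double_positive.all()
    _t, truth0, _m = gen_tracks(geo, 40, 0.0, small_config, seed=5, render=False)
    cargo0 = truth0[truth0.kind == "cargo"]
    assert not cargo0.double_positive.any()
    # marker-only tracks are never labeled double-positive
    assert not truth1[truth1.kind == "marker_only"].double_positive.any()


def test_gen_tracks_binomial_truth(small_field, small_config):
    geo, _ = small_field
    _t, truth, _m = gen_tracks(geo, 2000, 0.5, small_config, seed=6, render=False)
    cargo = truth[truth.kind == "cargo"]
    assert len(cargo) == 2000
    k = cargo.double_positive.sum()
    assert abs(k - 1000) <= 3 * np.sqrt(2000 * 0.25)


def test_gen_tracks_positions_on_dendrite(small_field, small_config):
    geo, _ = small_field
    tset, _truth, _m = gen_tracks(geo, 10, 0.5, small_config, seed=7, render=False)
    from dtraf import arc_project
    for tr in tset.tracks:
        assert np.all(np.diff(tr.frames) > 0)
        proj = arc_project(tr.positions, geo)
        assert not proj.excluded.any()


def test_gen_tracks_marker_jitter_recorded(small_field, small_config):
    geo, _ = small_field
    tset, truth, _m = gen_tracks(geo, 30, 1.0, small_config, seed=8, render=False)
    dp_ids = set(truth[truth.double_positive].track_id)
    for tr in tset.tracks:
        if tr.track_id in dp_ids:
            assert "marker" in tr.channel_positions
            offsets = np.linalg.norm(
                tr.channel_positions["marker"] - tr.positions, axis=1)
            assert np.all(offsets < 6 * small_config.marker_jitter_um)


def test_gen_tracks_deterministic(small_field, small_config):
    geo, _ = small_field
    t1, tr1, _ = gen_tracks(geo, 8, 0.5, small_config, seed=9, render=False)
    t2, tr2, _ = gen_tracks(geo, 8, 0.5, small_config, seed=9, render=False)
    assert tr1.equals(tr2)
    for a, b in zip(t1.tracks, t2.tracks):
        assert np.array_equal(a.positions, b.positions)


# ----------------------------------------------------------- gen_photoconversion

def test_photoconversion_amplitudes(small_field):
    geo, _ = small_field
    lam = 10.0
    red, green, truth = gen_photoconversion(geo, (10.0, 30.0), lam, 1000.0, seed=0)
    np.testing.assert_allclose(
        red.intensities, 1000.0 * np.exp(-truth.distance_um / lam))
    inside = truth.distance_um == 0
    assert inside.any()
    np.testing.assert_allclose(red.intensities[inside.to_numpy()], 1000.0)
    np.testing.assert_allclose(green.intensities, 1000.0)


def test_photoconversion_exp_decay_value(small_field):
    # punctum pinned at arc 53 um with zone (10, 30): distance 23, lambda 10
    geo, _ = small_field
    red, _g, truth = gen_photoconversion(
        geo, (10.0, 30.0), 10.0, 1000.0, seed=0, n_puncta=1,
        arc_range_um=(53.0, 53.0))
    assert truth.distance_um.iloc[0] == pytest.approx(23.0)
    assert red.intensities[0] == pytest.approx(1000.0 * 0.1003, rel=1e-3)


def test_photoconversion_zone_validation(small_field):
    geo, _ = small_field
    with pytest.raises(ValueError):
        gen_photoconversion(geo, (30.0, 10.0), 10.0, 1000.0)
    with pytest.raises(ValueError):
        gen_photoconversion(geo, (10.0, 30.0), -1.0, 1000.0)


# --------------------------------------------------------------- gen_spine_field

def test_spine_field_extremes(small_field, small_config):
    geo, mask = small_field
    _rois, truth, _img = gen_spine_field(geo, 1.0, 1.0, small_config,
                                         seed=0, mask=mask, render=False)
    assert truth.re_positive.all() and truth.cargo_positive.all()
    _rois, truth, _img = gen_spine_field(geo, 0.5, 0.0, small_config,
                                         seed=0, mask=mask, render=False)
    assert not truth.cargo_positive.any()


def test_spine_field_binomial_marginals(small_config):
    # 2000-spine geometry built directly (no raster needed without rendering)
    den = Dendrite(np.array([[0.0, 5.0], [4000.0, 5.0]]), np.array([1.0, 1.0]))
    spines = [Spine(0, 2.0 * (i + 1), 1 if i % 2 == 0 else -1, 0.4)
              for i in range(2000)]
    geo = DendriteGeometry((2.0, 5.0), 1.5, [den], spines)
    _rois, truth, _img = gen_spine_field(geo, 0.48, 0.206, small_config,
                                         seed=1, render=False)
    k_re = truth.re_positive.sum()
    assert abs(k_re - 2000 * 0.48) <= 3 * np.sqrt(2000 * 0.48 * 0.52)
    gain = truth[truth.re_positive].cargo_positive
    assert abs(gain.mean() - 0.206) <= 3 * np.sqrt(0.206 * 0.794 / len(gain))


def test_spine_field_requires_spines(small_config):
    geo = DendriteGeometry((2.0, 5.0), 1.5, [], [])
    with pytest.raises(ValueError):
        gen_spine_field(geo, 0.5, 0.5, small_config, render=False)


# ------------------------------------------------------------ gen_delivery_course

def test_delivery_course_baseline_and_plateau():
    kinetics = {"plateau": 3.0, "tau_h": 2.0, "delay_h": 1.0}
    table, truth = gen_delivery_course(kinetics, [0.0, 1.0, 1000.0], 5, 0.0, seed=0)
    rel = table[table.condition == "release"]
    # fold 1.0 at and before the delay -> raw = 100 + 10
    assert np.allclose(rel[rel.timepoint_h <= 1.0].raw_mean, 110.0)
    # late time approaches the plateau fold
    assert np.allclose(rel[rel.timepoint_h == 1000.0].raw_mean, 310.0)
    ctrl = table[table.condition == "no-release"]
    assert np.allclose(ctrl.raw_mean, 110.0)


def test_delivery_course_one_tau_rise():
    kinetics = {"plateau": 3.0, "tau_h": 2.0, "delay_h": 0.0}
    table, _ = gen_delivery_course(kinetics, [2.0], 3, 0.0, seed=0)
    rel = table[table.condition == "release"]
    fold = (rel.raw_mean - 10.0) / 100.0
    assert np.allclose(fold, 1.0 + 2.0 * (1.0 - np.exp(-1.0)))


def test_delivery_course_validation():
    with pytest.raises(ValueError):
        gen_delivery_course({"plateau": -1.0, "tau_h": 1.0}, [0.0], 3, 0.1)
    with pytest.raises(ValueError):
        gen_delivery_course({"plateau": 1.0, "tau_h": 1.0}, [-1.0], 3, 0.1)
    with pytest.raises(ValueError):
        gen_delivery_course({"plateau": 1.0, "tau_h": 1.0}, [0.0], 0, 0.1)
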