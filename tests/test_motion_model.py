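"""Dual-channel registration, model assembly and surrogate alignment."""

import numpy as np
import pytest

from crmoco import motion_model as mm
from crmoco import phantom as ph
from crmoco._utils import compose_fields, warp_image


@pytest.fixture(scope="module")
def channels(desk_phantom):
    return desk_phantom.water, desk_phantom.fat


def _translate(img, dy_px, dx_px, px):
    d = np.zeros((2, *img.shape))
    d[0] = dy_px * px
    d[1] = dx_px * px
    return warp_image(img, d, px)


def test_identity_registration_near_zero(channels):
    w, f = channels
    res = mm.register_pair((w, f), (w, f), mm.RegistrationConfig(iterations=30),
                           pixel_size=2.0)
    assert np.mean(res.field.magnitude()) / 2.0 < 0.1


@pytest.mark.parametrize("similarity", ["ssd", "nmi"])
def test_translation_recovery(channels, similarity):
    w, f = channels
    px = 2.0
    w2 = _translate(w, 3.0, -2.0, px)
    f2 = _translate(f, 3.0, -2.0, px)
    res = mm.register_pair((w, f), (w2, f2),
                           mm.RegistrationConfig(similarity=similarity), pixel_size=px)
    mask = w > 0
    dy = res.field.disp[0][mask].mean() / px
    dx = res.field.disp[1][mask].mean() / px
    assert abs(dy - 3.0) < 0.5 and abs(dx - (-2.0)) < 0.5


def test_uninformative_fat_channel_still_recovers(channels):
    """Fat replaced by constant noise: the water term dominates and the
    translation is still recovered within 1 px."""
    w, _ = channels
    px = 2.0
    rng = np.random.default_rng(5)
    f_noise = rng.uniform(0, 0.5, w.shape)
    w2 = _translate(w, 3.0, -2.0, px)
    f2 = rng.uniform(0, 0.5, w.shape)
    res = mm.register_pair((w, f_noise), (w2, f2),
                           mm.RegistrationConfig(similarity="nmi"), pixel_size=px)
    mask = w > 0
    assert abs(res.field.disp[0][mask].mean() / px - 3.0) < 1.0
    assert abs(res.field.disp[1][mask].mean() / px + 2.0) < 1.0


def test_degenerate_channel_falls_back_with_warning(channels):
    w, _ = channels
    px = 2.0
    const = np.zeros_like(w)
    with pytest.warns(RuntimeWarning, match="constant channel"):
        res = mm.register_pair((w, const), (_translate(w, 2.0, 0.0, px), const),
                               mm.RegistrationConfig(similarity="nmi"), pixel_size=px)
    assert abs(res.field.disp[0][w > 0].mean() / px - 2.0) < 0.5


def test_cost_decomposition_identity(channels):
    w, f = channels
    res = mm.register_pair((w, f), (_translate(w, 1.0, 1.0, 2.0),
                                    _translate(f, 1.0, 1.0, 2.0)),
                           mm.RegistrationConfig(iterations=15), pixel_size=2.0)
    ww, wf, r = res.weights
    assert res.cost == pytest.approx(ww * res.sim_water + wf * res.sim_fat
                                     + r * res.regulariser, abs=1e-9)


def test_nmi_maximal_at_self(channels):
    w, _ = channels
    base = mm.nmi(w, w, 32)
    for dy, dx in [(-5, 0), (-2, 3), (1, 1), (4, -4), (5, 5)]:
        shifted = _translate(w, dy, dx, 2.0)
        assert base >= mm.nmi(shifted, w, 32)


def test_inverse_consistency_on_translation(channels):
    w, f = channels
    px = 2.0
    w2, f2 = _translate(w, 2.0, -1.0, px), _translate(f, 2.0, -1.0, px)
    cfg = mm.RegistrationConfig(similarity="ssd")
    fwd = mm.register_pair((w, f), (w2, f2), cfg, pixel_size=px)
    bwd = mm.register_pair((w2, f2), (w, f), cfg, pixel_size=px)
    mask = w > 0
    s = fwd.field.disp + bwd.field.disp
    rms = np.sqrt(np.mean((s[:, mask] / px) ** 2))
    assert rms < 0.5


def test_build_model_from_true_bin_images(desk_phantom):
    """Per-bin mean diaphragm displacement of the estimated model is
    monotone in the bin amplitude order, and the model reduces the image
    difference to the reference by >= 50% (aggregate)."""
    p = desk_phantom
    amps = [0.0, 2.0, 5.0, 9.0, 13.0, 15.0]
    series = []
    for a in amps:
        _, _, maps, _ = ph.deform(p, a, 0.0)
        series.append((maps["water"], maps["fat"]))
    model = mm.build_model(series, 0, mm.RegistrationConfig(similarity="ssd"),
                           motion_type="respiratory")
    assert np.all(model.fields[0].disp == 0)
    rows = slice(int(p.diaphragm_row) - 2, int(p.diaphragm_row) + 3)
    dys = [f.disp[0][rows].mean() for f in model.fields]
    assert np.all(np.diff(dys) < 0)  # increasingly negative pull-back shift
    num = den = 0.0
    ref = series[0][0]
    for b, a in enumerate(amps[1:], start=1):
        tgt = series[b][0]
        num += np.mean((model.fields[b].warp(ref) - tgt) ** 2)
        den += np.mean((ref - tgt) ** 2)
    assert 1.0 - np.sqrt(num / den) >= 0.5


def test_build_model_identical_bins_zero(channels):
    w, f = channels
    model = mm.build_model([(w, f), (w, f)], 0,
                           mm.RegistrationConfig(iterations=20, similarity="ssd"),
                           motion_type="cardiac")
    for fld in model.fields:
        assert np.max(np.abs(fld.disp)) / 2.0 < 0.1


def test_build_model_empty_bin_copies_neighbour(channels):
    w, f = channels

    class Img:
        def __init__(self, w, f, empty=False):
            self.water, self.fat, self.empty, self.pixel_size = w, f, empty, 2.0

    shifted = Img(_translate(w, 2.0, 0.0, 2.0), _translate(f, 2.0, 0.0, 2.0))
    series = [Img(w, f), shifted, Img(w * 0, f * 0, empty=True)]
    model = mm.build_model(series, 0, mm.RegistrationConfig(similarity="ssd"),
                           motion_type="respiratory")
    assert 2 in model.flags
    assert np.array_equal(model.fields[2].disp, model.fields[1].disp)


def test_select_reference():
    t = np.linspace(0, 40, 2000)
    exhale_dom = np.sin(np.pi * t / 4.0) ** 4  # low most of the time
    assert mm.select_reference(exhale_dom) == "end_exhale"
    assert mm.select_reference(1.0 - exhale_dom) == "end_inhale"
    assert mm.select_reference(np.array([0.0, 1.0])) == "end_exhale"  # tie


def test_concatenate_identity_and_translation():
    px = 2.0
    shape = (2, 16, 16)
    z = mm.DisplacementField(np.zeros(shape), px)
    t1 = np.zeros(shape)
    t1[0] = 3.0
    t2 = np.zeros(shape)
    t2[1] = -2.0
    resp = mm.MotionModel(fields=[z, mm.DisplacementField(t1, px)], reference=0,
                          motion_type="respiratory")
    card_zero = mm.MotionModel(fields=[mm.DisplacementField(np.zeros(shape), px)],
                               reference=0, motion_type="cardiac")
    cr = mm.concatenate(resp, card_zero)
    assert np.allclose(cr.fields[1].disp, t1)
    # pure translations compose to the vector sum away from the boundary
    cr2_field = compose_fields(t1, t2, px)
    interior = (slice(4, 12), slice(4, 12))
    assert np.allclose(cr2_field[0][interior], 3.0, atol=1e-6)
    assert np.allclose(cr2_field[1][interior], -2.0, atol=1e-6)


def test_concatenate_matches_ground_truth(desk_phantom):
    p = desk_phantom
    px = p.pixel_size
    resp_f = mm.DisplacementField(ph.motion_field(p, 12.0, 0.0).disp, px)
    card_f = mm.DisplacementField(ph.motion_field(p, 0.0, 0.4).disp, px)
    z = mm.DisplacementField(np.zeros_like(resp_f.disp), px)
    resp = mm.MotionModel(fields=[z, resp_f], reference=0, motion_type="respiratory")
    card = mm.MotionModel(fields=[mm.DisplacementField(np.zeros_like(card_f.disp), px),
                                  card_f], reference=0, motion_type="cardiac")
    cr = mm.concatenate(resp, card)
    direct = ph.motion_field(p, 12.0, 0.4).disp
    rms = np.sqrt(np.mean((cr.fields[3].disp - direct) ** 2)) / px
    assert rms < 0.5


def test_concatenate_grid_mismatch_errors():
    px = 2.0
    a = mm.MotionModel(fields=[mm.DisplacementField(np.zeros((2, 8, 8)), px)],
                       reference=0, motion_type="respiratory")
    b = mm.MotionModel(fields=[mm.DisplacementField(np.zeros((2, 9, 9)), px)],
                       reference=0, motion_type="cardiac")
    with pytest.raises(ValueError, match="grid"):
        mm.concatenate(a, b)


def test_align_belt_delayed_copy(desk_surrogates):
    s = desk_surrogates
    fs = s.fs
    k = int(round(0.4 * fs))
    nav = np.roll(s.belt, k)  # nav(t) = belt(t - 0.4)
    shift = mm.align_belt(s.belt[100:-100], nav[100:-100], fs, max_shift=2.0)
    assert shift == pytest.approx(0.4, abs=1.0 / fs + 1e-9)
    assert mm.align_belt(s.belt, s.belt, fs, max_shift=2.0) == 0.0


def test_align_belt_recovers_generator_lag(desk_surrogates, desk_config):
    shift = mm.align_belt(desk_surrogates.belt, desk_surrogates.selfnav,
                          desk_surrogates.fs, max_shift=desk_config.resp_period)
    assert abs(shift - (-desk_config.belt_lag)) <= 1.0 / desk_surrogates.fs + 1e-9
    assert abs(shift) < desk_config.resp_period


def test_align_belt_range_error(desk_surrogates):
    with pytest.raises(ValueError, match="half"):
        mm.align_belt(desk_surrogates.belt[:100], desk_surrogates.selfnav[:100],
                      desk_surrogates.fs, max_shift=10.0)


def test_assign_bins_clamps_and_stationary(desk_surrogates):
    s = desk_surrogates
    half = s.time[-1] / 2
    in_win = s.time <= half
    vals = s.belt[in_win]
    edges = np.quantile(vals, np.arange(1, 6) / 6)
    rng_range = (float(vals.min()), float(vals.max()))
    # above-threshold values clamp into the last bin
    r_idx, _, n_cl = mm.assign_bins(np.array([1.0]), s.time,
                                    np.full_like(s.belt, 1e6), 0.0, edges,
                                    rng_range, s.r_peaks, 12)
    assert r_idx[0] == 5 and n_cl == 1
    # outside-window occupancy matches inside within 10% per bin
    t_in = s.time[in_win][::4]
    t_out = s.time[~in_win][::4]
    ri, _, _ = mm.assign_bins(t_in, s.time, s.belt, 0.0, edges, rng_range,
                              s.r_peaks, 12)
    ro, _, _ = mm.assign_bins(t_out, s.time, s.belt, 0.0, edges, rng_range,
                              s.r_peaks, 12)
    hi = np.bincount(ri, minlength=6) / ri.size
    ho = np.bincount(ro, minlength=6) / ro.size
    assert np.all(np.abs(hi - ho) < 0.10)


def test_model_reference_field_must_be_zero():
    px = 2.0
    bad = np.ones((2, 8, 8))
    with pytest.raises(ValueError, match="reference"):
        mm.MotionModel(fields=[mm.DisplacementField(bad, px)], reference=0,
                       motion_type="respiratory")
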