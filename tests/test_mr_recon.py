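"""k-space binning and iterative water/fat reconstruction."""

import numpy as np
import pytest

from crmoco import mr_recon, mr_sim, motion_model as mm
from crmoco import phantom as ph


def _moving_ks(seed=0, spokes=600, samples=48):
    cfg = ph.PhantomConfig(grid_shape=(32, 32), pixel_size=3.0, duration=240.0,
                           mr_window=120.0, seed=seed)
    p = ph.build_phantom(cfg)
    s = ph.generate_surrogates(cfg)
    mcfg = mr_sim.MRSequenceConfig(spokes_total=spokes, samples_per_spoke=samples,
                                   noise_sd=0.0, spoke_stride=int(120 / (spokes * 0.00757)))
    traj = mr_sim.make_trajectory(mcfg, s.mr_window, cfg.pixel_size)
    ks = mr_sim.simulate_acquisition(p, s, mcfg, traj)
    return p, s, ks


@pytest.fixture(scope="module")
def moving_chain():
    return _moving_ks()


def test_respiratory_bins_equal_count(moving_chain):
    _, s, ks = moving_chain
    binned = mr_recon.bin_kspace(ks, s, mr_recon.BinningSpec(n_resp=6), "respiratory")
    assert binned.occupancy.sum() == ks.trajectory.n_spokes
    assert np.all(np.abs(binned.occupancy - 100) <= 1)
    assert binned.thresholds.size == 5


def test_constant_belt_single_bin(moving_chain):
    p, s, ks = moving_chain
    import copy

    s2 = copy.copy(s)
    s2.belt = np.zeros_like(s.belt)
    with pytest.warns(RuntimeWarning):
        binned = mr_recon.bin_kspace(ks, s2, mr_recon.BinningSpec(n_resp=6), "respiratory")
    assert binned.occupancy[0] == ks.trajectory.n_spokes
    assert np.all(binned.occupancy[1:] == 0)


def test_cardiac_bins_partition(moving_chain):
    _, s, ks = moving_chain
    binned = mr_recon.bin_kspace(ks, s, mr_recon.BinningSpec(n_card=12), "cardiac")
    assert binned.occupancy.sum() == ks.trajectory.n_spokes
    all_idx = np.sort(np.concatenate(binned.bins))
    assert np.array_equal(all_idx, np.arange(ks.trajectory.n_spokes))


def test_binning_consistent_with_assign_bins(moving_chain):
    """Spokes inside the MR window get the same respiratory bin from
    bin_kspace and from the extension mapper using the stored thresholds."""
    _, s, ks = moving_chain
    binned = mr_recon.bin_kspace(ks, s, mr_recon.BinningSpec(n_resp=6), "respiratory")
    r_idx, _, _ = mm.assign_bins(ks.trajectory.times, s.time, s.belt, 0.0,
                                 binned.thresholds, binned.amplitude_range,
                                 s.r_peaks, 12)
    by_bin = np.empty(ks.trajectory.n_spokes, dtype=int)
    for b, idx in enumerate(binned.bins):
        by_bin[idx] = b
    assert np.array_equal(by_bin, r_idx)


def test_single_bin_water_only_accuracy(static_phantom, static_surrogates):
    """Noiseless fully sampled water-only phantom: |I_W| within 2% of the
    truth and fat leakage below 2%."""
    p2 = ph.build_phantom(static_phantom.config)
    p2.fat[:] = 0.0
    cfg = mr_sim.MRSequenceConfig(spokes_total=80, samples_per_spoke=80, noise_sd=0.0)
    traj = mr_sim.make_trajectory(cfg, static_surrogates.mr_window, p2.pixel_size)
    ks = mr_sim.simulate_acquisition(p2, static_surrogates, cfg, traj)
    binned = mr_recon.bin_kspace(ks, static_surrogates,
                                 mr_recon.BinningSpec(n_resp=1), "respiratory")
    img = mr_recon.reconstruct_waterfat(binned, p2.config.grid_shape, p2.pixel_size,
                                        mr_recon.MRReconConfig(iterations=60))[0]
    w, f = np.abs(img.water), np.abs(img.fat)
    assert np.linalg.norm(w - p2.water) / np.linalg.norm(p2.water) < 0.02
    assert f.mean() < 0.02 * w.mean()


def test_single_bin_fat_only_roles_swap(static_phantom, static_surrogates):
    p2 = ph.build_phantom(static_phantom.config)
    p2.water[:] = 0.0
    truth = p2.fat.copy()
    cfg = mr_sim.MRSequenceConfig(spokes_total=80, samples_per_spoke=80, noise_sd=0.0)
    traj = mr_sim.make_trajectory(cfg, static_surrogates.mr_window, p2.pixel_size)
    ks = mr_sim.simulate_acquisition(p2, static_surrogates, cfg, traj)
    binned = mr_recon.bin_kspace(ks, static_surrogates,
                                 mr_recon.BinningSpec(n_resp=1), "respiratory")
    img = mr_recon.reconstruct_waterfat(binned, p2.config.grid_shape, p2.pixel_size,
                                        mr_recon.MRReconConfig(iterations=60))[0]
    assert np.linalg.norm(np.abs(img.fat) - truth) / np.linalg.norm(truth) < 0.02
    assert np.abs(img.water).mean() < 0.02 * np.abs(img.fat).mean()


def test_two_echo_closed_form(static_phantom, static_surrogates):
    """In/opposed-phase echoes (phasors +1 and -1): the joint water/fat
    solution matches the half-sum/half-difference of independent per-echo
    reconstructions to 1e-6 relative."""
    p = static_phantom
    df = -428.0
    te1 = 1.0 / abs(df)  # exp(2 pi i df te1) = +1 (full cycle)
    te2 = te1 + 0.5 / abs(df)  # -1 (opposed phase)
    cfg = mr_sim.MRSequenceConfig(te=(te1, te2), spokes_total=80,
                                  samples_per_spoke=80, noise_sd=0.0)
    np.testing.assert_allclose(cfg.echo_phasors, [1.0, -1.0], atol=1e-12)
    traj = mr_sim.make_trajectory(cfg, static_surrogates.mr_window, p.pixel_size)
    ks = mr_sim.simulate_acquisition(p, static_surrogates, cfg, traj)
    binned = mr_recon.bin_kspace(ks, static_surrogates,
                                 mr_recon.BinningSpec(n_resp=1), "respiratory")
    rcfg = mr_recon.MRReconConfig(iterations=200, reg_weight=0.0, tol=1e-16)
    img = mr_recon.reconstruct_waterfat(binned, p.config.grid_shape, p.pixel_size,
                                        rcfg)[0]

    # oracle: reconstruct each echo image independently with the same
    # solver (single compound channel), then half-sum / half-difference
    def echo_image(e):
        cfg_e = mr_sim.MRSequenceConfig(te=(te1, te1 + 1e-9), spokes_total=80,
                                        samples_per_spoke=80, noise_sd=0.0)
        ks_e = mr_sim.KSpace(data=np.repeat(ks.data[e:e + 1], 2, axis=0),
                             trajectory=traj, config=cfg_e)
        b_e = mr_recon.BinnedKSpace(kspace=ks_e, bins=binned.bins, mode="respiratory",
                                    occupancy=binned.occupancy)
        out = mr_recon.reconstruct_waterfat(b_e, p.config.grid_shape, p.pixel_size,
                                            rcfg)[0]
        return out.water + out.fat  # both phasors ~ +1: compound image

    i1 = echo_image(0)
    i2 = echo_image(1)
    w_cf = (i1 + i2) / 2
    f_cf = (i1 - i2) / 2
    scale = np.linalg.norm(w_cf)
    assert np.linalg.norm(img.water - w_cf) / scale < 1e-6
    assert np.linalg.norm(img.fat - f_cf) / scale < 1e-6


def test_residual_monotone(single_bin, static_phantom):
    from crmoco.mr_recon import MRReconConfig, _System, _cgls

    cfg = MRReconConfig(iterations=25, tol=0.0)
    system = _System(single_bin, static_phantom.config.grid_shape,
                     static_phantom.pixel_size, cfg)
    _, _, hist = _cgls(system, cfg)
    assert np.all(np.diff(hist) <= 1e-9 * hist[0])


def test_identity_motion_model_matches_per_bin(single_bin, static_phantom):
    shape = static_phantom.config.grid_shape
    px = static_phantom.pixel_size
    cfg = mr_recon.MRReconConfig(iterations=40)
    per_bin = mr_recon.reconstruct_waterfat(single_bin, shape, px, cfg)[0]
    ident = mm.MotionModel(fields=[mm.DisplacementField(np.zeros((2, *shape)), px)],
                           reference=0, motion_type="respiratory")
    joint = mr_recon.reconstruct_waterfat(single_bin, shape, px, cfg, motion=ident)
    assert np.allclose(joint.water, per_bin.water, atol=1e-8)
    assert np.allclose(joint.fat, per_bin.fat, atol=1e-8)


def test_empty_bins_flagged_and_all_empty_errors(moving_chain, static_phantom):
    _, s, ks = moving_chain
    binned = mr_recon.bin_kspace(ks, s, mr_recon.BinningSpec(n_resp=6), "respiratory")
    sub = mr_recon.BinnedKSpace(kspace=ks, bins=[np.array([], dtype=int),
                                                 binned.bins[0]],
                                mode="respiratory", occupancy=np.array([0, 100]))
    out = mr_recon.reconstruct_waterfat(sub, (32, 32), 3.0,
                                        mr_recon.MRReconConfig(iterations=2))
    assert out[0].empty and not out[1].empty
    empty = mr_recon.BinnedKSpace(kspace=ks, bins=[np.array([], dtype=int)],
                                  mode="respiratory", occupancy=np.array([0]))
    with pytest.raises(ValueError):
        mr_recon.reconstruct_waterfat(empty, (32, 32), 3.0,
                                      mr_recon.MRReconConfig(iterations=2),
                                      motion=mm.MotionModel(
                                          fields=[mm.DisplacementField(
                                              np.zeros((2, 32, 32)), 3.0)],
                                          reference=0, motion_type="respiratory"))


def test_motion_reconstruction_sharper_than_average():
    """Motion-aware reconstruction of a two-state moving phantom has a
    sharper myocardial boundary than the motion-averaged reconstruction."""
    cfg = ph.PhantomConfig(grid_shape=(32, 32), pixel_size=3.0, resp_amplitude=12.0,
                           cardiac_contraction_fraction=0.0, duration=240.0,
                           mr_window=120.0, seed=0, resp_taper="uniform")
    p = ph.build_phantom(cfg)
    s = ph.generate_surrogates(cfg)
    mcfg = mr_sim.MRSequenceConfig(spokes_total=320, samples_per_spoke=64,
                                   noise_sd=0.0, spoke_stride=49)
    traj = mr_sim.make_trajectory(mcfg, s.mr_window, cfg.pixel_size)
    ks = mr_sim.simulate_acquisition(p, s, mcfg, traj)
    binned = mr_recon.bin_kspace(ks, s, mr_recon.BinningSpec(n_resp=2), "respiratory")
    rcfg = mr_recon.MRReconConfig(iterations=25)
    # ground-truth fields at the two bins' mean amplitudes
    d = np.interp(traj.times, s.time, s.diaphragm_mm)
    fields = []
    for b in range(2):
        amp = float(np.clip(d[binned.bins[b]].mean(), 0, 12))
        fields.append(mm.DisplacementField(ph.motion_field(p, amp, 0.0).disp,
                                           cfg.pixel_size))
    a0 = float(np.clip(d[binned.bins[0]].mean(), 0, 12))
    fields[0] = mm.DisplacementField(np.zeros((2, 32, 32)), cfg.pixel_size)
    model = mm.MotionModel(fields=fields, reference=0, motion_type="respiratory")
    mc = mr_recon.reconstruct_waterfat(binned, (32, 32), 3.0, rcfg, motion=model)
    avg_bin = mr_recon.BinnedKSpace(kspace=ks,
                                    bins=[np.arange(ks.trajectory.n_spokes)],
                                    mode="respiratory", occupancy=np.array([320]))
    avg = mr_recon.reconstruct_waterfat(avg_bin, (32, 32), 3.0, rcfg)[0]
    # edge gradient magnitude at the myocardial boundary (reference state)
    lab0, _, _, _ = ph.deform(p, a0, 0.0)
    from scipy import ndimage

    myo = lab0 == ph.MYO
    edge = ndimage.binary_dilation(myo, iterations=1) & ~myo

    def grad_at_edge(img):
        gy, gx = np.gradient(np.abs(img.water))
        return np.hypot(gy, gx)[edge].mean()

    assert grad_at_edge(mc) > grad_at_edge(avg)


def test_waterfat_io_roundtrip(tmp_path, single_bin, static_phantom):
    img = mr_recon.reconstruct_waterfat(single_bin, (32, 32), 3.0,
                                        mr_recon.MRReconConfig(iterations=3))[0]
    mr_recon.save_waterfat(img, tmp_path, "bin0")
    from crmoco._utils import load_nifti

    re, px = load_nifti(tmp_path / "bin0_water_real.nii.gz")
    im, _ = load_nifti(tmp_path / "bin0_water_imag.nii.gz")
    assert np.allclose(re + 1j * im, img.water)
    assert px == 3.0
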