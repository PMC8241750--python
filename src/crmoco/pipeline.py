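"""End-to-end workflow orchestration.

Stage order: phantom + surrogates -> MR acquisition -> belt/self-navigator
alignment -> respiratory binning and per-bin water/fat reconstruction ->
respiratory motion model -> cardiac binning with respiration-corrected
reconstructions -> cardiac motion model -> concatenated cardiorespiratory
model -> motion-compensated MR reconstruction -> 4-tissue attenuation map
-> PET acquisition -> AVG and cr-MCIR OSEM -> hotspot quantification.

Every stage persists its artifacts under the output directory and is
recorded (file hashes, wall time, config snapshot) in a YAML run manifest;
a re-run with the same seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atten, metrics, motion_model as mm, mr_recon, mr_sim, pet_recon, pet_sim
from . import phantom as ph

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    phantom: ph.PhantomConfig = dc_field(default_factory=ph.PhantomConfig)
    mr: mr_sim.MRSequenceConfig = dc_field(default_factory=mr_sim.MRSequenceConfig)
    binning: mr_recon.BinningSpec = dc_field(default_factory=mr_recon.BinningSpec)
    mr_recon: mr_recon.MRReconConfig = dc_field(default_factory=mr_recon.MRReconConfig)
    registration: mm.RegistrationConfig = dc_field(default_factory=mm.RegistrationConfig)
    plan: pet_sim.AcquisitionPlan = dc_field(default_factory=pet_sim.AcquisitionPlan)
    osem: pet_recon.OSEMConfig = dc_field(default_factory=pet_recon.OSEMConfig)
    outdir: str = "run"
    seed: int = 0
    mode: str = "cr-mcir"  # "avg" | "r-mcir" | "cr-mcir"

    def propagate_seed(self):
        self.phantom.seed = self.seed
        self.plan.seed = self.seed


@dataclass
class RunManifest:
    stages: dict = dc_field(default_factory=dict)
    seed: int = 0

    def record(self, name: str, outputs: dict, t0: float):
        self.stages[name] = {
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: _sha256(v) for k, v in outputs.items()},
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, "stages": self.stages}, fh)


def _sha256(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    else:
        h.update(repr(obj).encode())
    return h.hexdigest()[:16]


def true_mu_map(labels: np.ndarray, pixel_size: float) -> atten.MuMap:
    """Ground-truth attenuation of a phantom label map (for simulation):
    air -> 0, lung -> lung, fat -> fat, everything else (incl. the stent
    void) -> soft tissue."""
    table = atten.MuAssignment().mu
    mu = np.full(labels.shape, table[atten.CLS_SOFT])
    mu[labels == ph.AIR] = table[atten.CLS_AIR]
    mu[labels == ph.LUNG] = table[atten.CLS_LUNG]
    mu[labels == ph.FAT] = table[atten.CLS_FAT]
    return atten.MuMap(mu=mu, pixel_size=pixel_size, provenance="static")


def default_rois(phan: ph.DynamicPhantom, profile_len_mm: float = 45.0) -> metrics.ROISpec:
    """Plaque/background ROIs and the profile line from the (reference)
    phantom geometry: a box around the plaque, a blood-pool box inside
    the ventricle, and a profile through the plaque along the dominant
    (superior-inferior) motion direction."""
    lab = phan.labels
    py, px_ = np.nonzero(lab == ph.PLAQUE)
    cy, cx = float(py.mean()), float(px_.mean())
    ny, nx = lab.shape
    hy, hx = phan.heart_center
    direction = np.array([cy - hy, cx - hx])
    direction /= np.linalg.norm(direction)
    # plaque box nudged outward (away from the myocardium/blood pool) the
    # way an observer would place it, so the in-ROI maximum is the plaque
    half = max(int(round(5.0 / phan.pixel_size)), 2)
    oc = np.array([cy, cx]) + direction * 1.5
    plaque_roi = (max(int(oc[0]) - half, 0), min(int(oc[0]) + half + 1, ny),
                  max(int(oc[1]) - half, 0), min(int(oc[1]) + half + 1, nx))
    # blood-pool background box inside the ventricle, offset away from the
    # plaque so the two ROIs stay disjoint
    bh = max(int(phan.heart_radius * 0.25), 2)
    bc = np.array([hy, hx]) - direction * 0.35 * phan.heart_radius
    bg_roi = (int(bc[0]) - bh, int(bc[0]) + bh + 1, int(bc[1]) - bh, int(bc[1]) + bh + 1)
    # the profile crosses the plaque along the superior-inferior axis, the
    # dominant motion direction: motion blurring spreads the hotspot along
    # this line, so its fitted width shrinks when motion is corrected
    # (the vessel runs transversely here, so this is also the
    # perpendicular-to-vessel direction)
    axis = np.array([1.0, 0.0])
    half_mm = profile_len_mm / 2.0
    c_mm = np.array([cy, cx]) * phan.pixel_size
    p0 = tuple(c_mm - axis * half_mm)
    p1 = tuple(c_mm + axis * half_mm)
    return metrics.ROISpec(plaque={"coronal": plaque_roi},
                           background={"coronal": bg_roi},
                           profile={"coronal": (p0, p1)})


def run_full(config: RunConfig) -> RunManifest:
    """Execute the complete workflow; returns the run manifest."""
    config.propagate_seed()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    px = config.phantom.pixel_size
    grid = config.phantom.grid_shape

    def stage(name):
        log.info("stage: %s", name)
        return time.time()

    # A: phantom + surrogates ---------------------------------------------
    t0 = stage("phantom")
    phan = ph.build_phantom(config.phantom)
    surr = ph.generate_surrogates(config.phantom)
    ph.save_phantom(phan, outdir / "phantom")
    surr.to_csv(outdir / "phantom" / "surrogates.csv", outdir / "phantom" / "rpeaks.csv")
    manifest.record("phantom", {"labels": phan.labels, "belt": surr.belt}, t0)

    # MR acquisition -------------------------------------------------------
    t0 = stage("mr_sim")
    traj = mr_sim.make_trajectory(config.mr, surr.mr_window, px)
    kspace = mr_sim.simulate_acquisition(phan, surr, config.mr, traj, seed=config.seed)
    mr_sim.save_kspace(kspace, outdir / "kspace.npz")
    manifest.record("mr_sim", {"kspace": kspace.data}, t0)

    # belt alignment -------------------------------------------------------
    t0 = stage("align")
    in_win = surr.time <= surr.mr_window[1]
    shift = mm.align_belt(surr.belt[in_win], surr.selfnav[in_win], surr.fs,
                          max_shift=config.phantom.resp_period)
    assert abs(shift) < config.phantom.resp_period
    manifest.record("align", {"shift": shift}, t0)

    # respiratory binning + motion-resolved reconstruction ------------------
    t0 = stage("resp_recon")
    resp_binned = mr_recon.bin_kspace(kspace, surr, config.binning, "respiratory",
                                      belt_shift=shift)
    resp_imgs = mr_recon.reconstruct_waterfat(resp_binned, grid, px, config.mr_recon)
    manifest.record("resp_recon", {"img0": resp_imgs[0].water}, t0)

    # respiratory motion model ---------------------------------------------
    t0 = stage("resp_model")
    belt_win = np.interp(kspace.trajectory.times - shift, surr.time, surr.belt)
    ref_state = mm.select_reference(belt_win)
    resp_ref = 0 if ref_state == "end_exhale" else config.binning.n_resp - 1
    resp_model = mm.build_model(resp_imgs, resp_ref, config.registration,
                                motion_type="respiratory",
                                thresholds=resp_binned.thresholds,
                                amplitude_range=resp_binned.amplitude_range)
    resp_model.time_shift = shift
    save_model(resp_model, outdir / "model_resp")
    manifest.record("resp_model", {"f1": resp_model.fields[-1].disp}, t0)

    if config.mode == "avg":
        model = None
    elif config.mode == "r-mcir":
        model = resp_model
        model.n_card = 1
        card_ref = 0
    else:
        # cardiac binning; respiration-corrected reconstruction per cardiac
        # bin (data split by respiratory state inside each cardiac bin, the
        # respiratory model applied in the encoding)
        t0 = stage("card_recon")
        card_binned = mr_recon.bin_kspace(kspace, surr, config.binning, "cardiac")
        card_imgs = []
        for j in range(config.binning.n_card):
            cell_bins = [np.intersect1d(resp_binned.bins[i], card_binned.bins[j])
                         for i in range(config.binning.n_resp)]
            sub = mr_recon.BinnedKSpace(
                kspace=kspace, bins=cell_bins, mode="cardiorespiratory",
                occupancy=np.array([b.size for b in cell_bins]),
            )
            if all(b.size == 0 for b in cell_bins):
                z = np.zeros(grid, dtype=np.complex128)
                card_imgs.append(mr_recon.WaterFatImage(z, z.copy(), j, px, empty=True))
                continue
            img = mr_recon.reconstruct_waterfat(sub, grid, px, config.mr_recon,
                                                motion=resp_model)
            img.bin_id = j
            card_imgs.append(img)
        manifest.record("card_recon", {"img0": card_imgs[0].water}, t0)

        # cardiac model; reference = end-diastole (phase bin 0)
        t0 = stage("card_model")
        card_ref = 0
        card_model = mm.build_model(card_imgs, card_ref, config.registration,
                                    motion_type="cardiac")
        save_model(card_model, outdir / "model_card")
        manifest.record("card_model", {"f1": card_model.fields[-1].disp}, t0)

        t0 = stage("concatenate")
        model = mm.concatenate(resp_model, card_model)
        manifest.record("concatenate", {"f1": model.fields[-1].disp}, t0)

    # motion-compensated MR reconstruction + AC map -------------------------
    t0 = stage("ac_map")
    if model is not None:
        if config.mode == "r-mcir":
            joint_bins = resp_binned.bins
        else:
            card_binned2 = mr_recon.bin_kspace(kspace, surr, config.binning, "cardiac")
            joint_bins = [
                np.intersect1d(resp_binned.bins[i], card_binned2.bins[j])
                for i in range(config.binning.n_resp)
                for j in range(config.binning.n_card)
            ]
        joint = mr_recon.BinnedKSpace(
            kspace=kspace, bins=joint_bins, mode="cardiorespiratory",
            occupancy=np.array([b.size for b in joint_bins]),
        )
        mc_img = mr_recon.reconstruct_waterfat(joint, grid, px, config.mr_recon,
                                               motion=model)
    else:
        mc_img = resp_imgs[resp_binned.occupancy.argmax()]
    mr_recon.save_waterfat(mc_img, outdir / "mr", "crmcir")
    classes = atten.segment_tissues(mc_img, seed=config.seed)
    classes = atten.inpaint_stent(classes)
    mu_ref = atten.assign_mu(classes)
    manifest.record("ac_map", {"mu": mu_ref.mu}, t0)

    # PET simulation (ground-truth attenuation per bin) ----------------------
    t0 = stage("pet_sim")
    sim_model = model if model is not None else _identity_model(resp_model, grid, px)
    n_bins = (len(sim_model.thresholds) + 1) * (sim_model.n_card or 1)
    geometry = pet_sim.PETGeometry(pixel_size=px)
    mu_true = []
    frames = _bin_states(phan, surr, sim_model, config.plan)
    for b in range(n_bins):
        resp_mm, phase = frames[b]
        lab_b, _, _, _ = ph.deform(phan, resp_mm, phase)
        mu_true.append(true_mu_map(lab_b, px))
    sinos = pet_sim.simulate(phan, surr, mu_true, config.plan, sim_model, geometry)
    manifest.record("pet_sim", {"counts": sinos.counts}, t0)

    # PET reconstruction -----------------------------------------------------
    t0 = stage("pet_recon")
    img_avg = pet_recon.osem_avg(sinos, mu_ref, config.osem, grid)
    pet_recon.save_pet(img_avg, outdir / "pet_avg.nii.gz")
    if model is not None:
        img_mc = pet_recon.osem_mcir(sinos, model, mu_ref, config.osem, grid)
        pet_recon.save_pet(img_mc, outdir / "pet_crmcir.nii.gz")
    else:
        img_mc = img_avg
    manifest.record("pet_recon", {"avg": img_avg.image, "mcir": img_mc.image}, t0)

    # quantification ---------------------------------------------------------
    t0 = stage("metrics")
    rois = default_rois(phan)
    row = metrics.measure_plaque(img_avg, img_mc, rois, px)
    table = pd.DataFrame([{"plaque": 1, **row}])
    table.to_csv(outdir / "study_table.csv", index=False)
    manifest.record("metrics", {"row": tuple(row.values())}, t0)

    manifest.save(outdir / "manifest.yaml")
    return manifest


def _identity_model(resp_model: mm.MotionModel, grid, px) -> mm.MotionModel:
    nb = resp_model.n_bins
    fields = [mm.DisplacementField(np.zeros((2, *grid)), px) for _ in range(nb)]
    return mm.MotionModel(fields=fields, reference=0, motion_type="respiratory",
                          thresholds=resp_model.thresholds,
                          amplitude_range=resp_model.amplitude_range,
                          time_shift=resp_model.time_shift, n_card=1)


def _bin_states(phan, surr, model, plan):
    """Mean true (resp_mm, phase) per combined bin over the PET frames."""
    n_card = model.n_card or 1
    n_bins = (len(model.thresholds) + 1) * n_card
    t = np.arange(0.0, plan.duration, plan.frame_duration) + plan.frame_duration / 2
    t = t[t < surr.time[-1]]
    r_idx, c_idx, _ = mm.assign_bins(t, surr.time, surr.belt, model.time_shift,
                                     model.thresholds, model.amplitude_range,
                                     surr.r_peaks, n_card)
    combined = r_idx * n_card + c_idx
    d_true = np.interp(t, surr.time, surr.diaphragm_mm)
    phase = ph.cardiac_phase(t, surr.r_peaks)
    out = {}
    for b in range(n_bins):
        m = combined == b
        if np.any(m):
            out[b] = (float(np.clip(d_true[m].mean(), 0, phan.config.resp_amplitude)),
                      float(np.clip(phase[m].mean(), 0, np.nextafter(1.0, 0.0))))
        else:
            out[b] = (0.0, 0.0)
    return out


def save_model(model: mm.MotionModel, outdir) -> None:
    from ._utils import save_nifti

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b, f in enumerate(model.fields):
        save_nifti(outdir / f"field_{b:03d}_dy.nii.gz", f.disp[0], f.pixel_size)
        save_nifti(outdir / f"field_{b:03d}_dx.nii.gz", f.disp[1], f.pixel_size)
    meta = {
        "reference": int(model.reference),
        "motion_type": model.motion_type,
        "convention": "pull-back mm: reference image sampled at x + d(x) gives the bin image",
        "time_shift_s": float(model.time_shift),
        "thresholds": None if model.thresholds is None else [float(v) for v in model.thresholds],
        "amplitude_range": None if model.amplitude_range is None else
            [float(v) for v in model.amplitude_range],
        "flags": {int(k): v for k, v in model.flags.items()},
    }
    with open(outdir / "model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
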