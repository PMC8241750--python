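"""Dynamic 2D thorax phantom with cardiorespiratory motion and surrogates.

The phantom is a coronal-like slice through the thorax: two lungs above the
diaphragm, a heart (myocardium ring + blood pool) between them, a
subcutaneous fat layer, soft tissue elsewhere and air outside the body.  A
small focal plaque with elevated tracer activity sits on the outer
myocardial boundary facing the lung, emulating a coronary [18F]NaF hotspot
close to the lung-soft tissue interface.  An optional stent is modelled as
an MR signal void (zero water and fat signal) with soft-tissue attenuation
and plaque-level activity.

Motion is analytic and therefore provides exact ground truth:

* respiration - superior-inferior translation with a smooth taper (zero at
  the chest apex, full amplitude at and below the diaphragm); the driving
  waveform is ``A * sin^4(pi t / T)`` so end-exhale is the prevalent state
* cardiac - radial contraction about the heart centre, tapered to zero just
  outside the myocardium; contraction is zero at the end-diastolic
  reference phase and maximal mid-cycle

Both deformations are monotone 1D maps (in the row resp. radial coordinate)
and are inverted numerically to machine precision, yielding the pull-back
displacement fields used everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from ._utils import rng_for, save_nifti, warp_image

# tissue label codes
AIR, LUNG, SOFT, FAT, MYO, BLOOD, PLAQUE, STENT = range(8)

LABEL_NAMES = {
    AIR: "air",
    LUNG: "lung",
    SOFT: "soft",
    FAT: "fat",
    MYO: "myocardium",
    BLOOD: "blood",
    PLAQUE: "plaque",
    STENT: "stent_void",
}

# per-tissue (activity, water signal, fat signal); activity of plaque and
# stent is filled in from the configured plaque-to-blood ratio.  The
# activity pattern follows the [18F]NaF biodistribution: myocardial uptake
# is low (blood-pool dominated), which is what makes focal plaque uptake
# measurable against the left-ventricle blood background.
_TISSUE = {
    AIR: (0.0, 0.0, 0.0),
    LUNG: (0.2, 0.15, 0.03),
    SOFT: (1.0, 1.0, 0.08),
    FAT: (0.4, 0.15, 0.95),
    MYO: (0.9, 1.0, 0.05),
    BLOOD: (1.2, 1.2, 0.02),
    PLAQUE: (None, 0.9, 0.05),
    STENT: (None, 0.0, 0.0),
}


class PhantomConfigError(ValueError):
    """Invalid phantom configuration; the message names the field."""


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 2.0  # mm
    resp_amplitude: float = 15.0  # mm, peak diaphragm excursion
    resp_period: float = 4.0  # s, mean cycle length
    resp_period_sd: float = 0.2  # s, cycle-to-cycle period jitter
    resp_amp_sd: float = 0.08  # relative cycle-to-cycle amplitude variation
    cardiac_rr_mean: float = 1.0  # s
    cardiac_rr_sd: float = 0.05  # s
    cardiac_contraction_fraction: float = 0.12
    plaque_diameter: float = 3.0  # mm
    # activity concentration of the micro-calcified plaque relative to the
    # blood pool; chosen so the ideal (static, noiseless) reconstruction at
    # the 2 mm voxel / 4 mm filter settings measures a TBR near the middle
    # of the clinically reported 1.1-3.4 range (partial volume of a 3 mm
    # focus implies underlying concentration ratios of order ten)
    plaque_to_blood_activity_ratio: float = 10.0
    stent_enabled: bool = False
    duration: float = 2700.0  # s, total (PET) scan
    mr_window: float = 720.0  # s, MR acquisition window starting at t=0
    seed: int = 0
    # surrogate generation
    surrogate_fs: float = 20.0  # Hz
    belt_lag: float = 0.3  # s, belt delay vs. true diaphragm motion
    belt_noise_sd: float = 0.02  # fraction of resp_amplitude
    selfnav_noise_sd: float = 0.02
    resp_taper: str = "smooth"  # "smooth" | "uniform" (pure translation)

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny < 16 or nx < 16:
            raise PhantomConfigError("grid_shape: must be at least 16x16")
        for name in ("pixel_size", "resp_period", "cardiac_rr_mean", "duration", "mr_window", "surrogate_fs", "plaque_diameter"):
            if getattr(self, name) <= 0:
                raise PhantomConfigError(f"{name}: must be > 0")
        if self.resp_amplitude < 0:
            raise PhantomConfigError("resp_amplitude: must be >= 0")
        extent = min(ny, nx) * self.pixel_size
        if self.resp_amplitude >= extent / 4:
            raise PhantomConfigError("resp_amplitude: must be < grid extent / 4")
        if self.plaque_diameter < self.pixel_size:
            raise PhantomConfigError("plaque_diameter: must span at least one pixel")
        if self.plaque_to_blood_activity_ratio <= 1:
            raise PhantomConfigError("plaque_to_blood_activity_ratio: must be > 1")
        if not 0 <= self.cardiac_contraction_fraction < 0.5:
            raise PhantomConfigError("cardiac_contraction_fraction: must be in [0, 0.5)")
        if self.mr_window > self.duration:
            raise PhantomConfigError("mr_window: must not exceed duration")
        if self.resp_taper not in ("smooth", "uniform"):
            raise PhantomConfigError("resp_taper: must be 'smooth' or 'uniform'")

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class MotionGroundTruth:
    """Exact pull-back displacement field (mm) for one motion state.

    ``disp[c]`` holds the c-component (0 = superior-inferior rows,
    1 = left-right columns) such that sampling the reference image at
    ``x + disp(x)`` yields the image in this state.  Zero at reference.
    """

    disp: np.ndarray  # (2, ny, nx) mm
    resp_mm: float
    cardiac_phase: float
    pixel_size: float


@dataclass
class DynamicPhantom:
    config: PhantomConfig
    labels: np.ndarray  # reference tissue label map (int)
    activity: np.ndarray  # reference activity map
    water: np.ndarray  # reference water signal
    fat: np.ndarray  # reference fat signal
    heart_center: tuple[float, float]  # px
    heart_radius: float  # px, outer myocardium radius
    diaphragm_row: float  # px
    apex_row: float  # px, superior taper-zero row
    fall_start: float  # px, row where the inferior taper starts falling
    fall_end: float  # px, row where the taper is back to zero
    resp_cycle_starts: np.ndarray = None  # s, start of each breathing cycle
    resp_cycle_periods: np.ndarray = None  # s
    resp_cycle_amps: np.ndarray = None  # relative amplitude per cycle, <= 1

    @property
    def pixel_size(self) -> float:
        return self.config.pixel_size

    # -- analytic respiratory waveform ------------------------------------
    def resp_waveform(self, t: np.ndarray) -> np.ndarray:
        """True diaphragm displacement (mm, inferior positive) at time t.

        Per breathing cycle k the excursion is
        ``A * r_k * sin^4(pi (t - t_k) / T_k)``: the quartic sine keeps
        end-exhale (zero displacement) the prevalent state while r_k and
        T_k vary from cycle to cycle, as real breathing does.  Negative
        times clamp to the first cycle.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = self.resp_cycle_starts
        k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
        u = (t - starts[k]) / self.resp_cycle_periods[k]
        u = np.clip(u, 0.0, 1.0)
        out = self.config.resp_amplitude * self.resp_cycle_amps[k] * np.sin(np.pi * u) ** 4
        return out

    def resp_taper(self, rows_px: np.ndarray) -> np.ndarray:
        """Spatial modulation of the respiratory shift: 0 above the chest
        apex, smoothstep up to 1 at the diaphragm, back to 0 towards the
        inferior body edge (the abdomen compresses; the pelvis is static),
        so no tissue is pushed through the field of view boundary."""
        rows_px = np.asarray(rows_px, dtype=float)
        if self.config.resp_taper == "uniform":
            return np.ones_like(rows_px)
        u = np.clip((rows_px - self.apex_row) / (self.diaphragm_row - self.apex_row), 0.0, 1.0)
        rise = 3 * u**2 - 2 * u**3
        v = np.clip((rows_px - self.fall_start) / (self.fall_end - self.fall_start), 0.0, 1.0)
        fall = 1.0 - (3 * v**2 - 2 * v**3)
        return rise * fall


@dataclass
class SurrogateSet:
    time: np.ndarray  # s, uniform
    belt: np.ndarray  # a.u.
    selfnav: np.ndarray  # mm-scale heart SI displacement + noise
    r_peaks: np.ndarray  # s, strictly increasing
    mr_window: tuple[float, float]
    fs: float
    diaphragm_mm: np.ndarray  # noise-free ground-truth diaphragm trace

    def to_csv(self, trace_path, rpeak_path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.time, "belt": self.belt, "selfnav": self.selfnav}).to_csv(
            trace_path, index=False
        )
        pd.DataFrame({"r_peak_s": self.r_peaks}).to_csv(rpeak_path, index=False)


# ---------------------------------------------------------------------------
# construction


def _ellipse(shape, center, semi) -> np.ndarray:
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


def build_phantom(config: PhantomConfig) -> DynamicPhantom:
    """Construct the reference-state phantom.  Deterministic for a fixed
    config (the seed only matters for the surrogate/noise streams)."""
    config.validate()
    ny, nx = config.grid_shape
    lab = np.full((ny, nx), AIR, dtype=np.int16)

    body_c = (0.50 * ny, 0.50 * nx)
    body_s = (0.44 * ny, 0.42 * nx)
    body = _ellipse((ny, nx), body_c, body_s)
    inner = _ellipse((ny, nx), body_c, (0.92 * body_s[0], 0.90 * body_s[1]))
    lab[body] = FAT
    lab[inner] = SOFT

    lungL = _ellipse((ny, nx), (0.34 * ny, 0.30 * nx), (0.20 * ny, 0.13 * nx))
    lungR = _ellipse((ny, nx), (0.32 * ny, 0.68 * nx), (0.22 * ny, 0.14 * nx))
    lab[(lungL | lungR) & inner] = LUNG

    heart_c = (0.46 * ny, 0.46 * nx)
    heart_r = 0.13 * ny
    blood_r = 0.085 * ny
    heart = _ellipse((ny, nx), heart_c, (heart_r, heart_r))
    blood = _ellipse((ny, nx), heart_c, (blood_r, blood_r))
    lab[heart] = MYO
    lab[blood] = BLOOD

    # plaque on the epicardial surface (coronary course): just outside the
    # myocardial boundary, facing the left lung
    ang = np.deg2rad(225.0)  # up-left in (row, col) with row axis downward
    pr = max(config.plaque_diameter / config.pixel_size / 2.0, 0.5)
    pc = (heart_c[0] + (heart_r + 0.5 * pr) * np.cos(ang),
          heart_c[1] + (heart_r + 0.5 * pr) * np.sin(ang))
    plaque = _ellipse((ny, nx), pc, (pr, pr))
    if not np.any(plaque):  # sub-pixel plaque: label the nearest pixel
        plaque[int(round(pc[0])), int(round(pc[1]))] = True
    lab[plaque] = PLAQUE

    if config.stent_enabled:
        sc = (0.72 * ny, 0.38 * nx)
        sr = max(3.0 / config.pixel_size, 1.5)
        lab[_ellipse((ny, nx), sc, (sr, sr))] = STENT

    plaque_act = config.plaque_to_blood_activity_ratio * _TISSUE[BLOOD][0]
    act = np.zeros((ny, nx))
    water = np.zeros((ny, nx))
    fatmap = np.zeros((ny, nx))
    for code, (a, w, f) in _TISSUE.items():
        m = lab == code
        act[m] = plaque_act if a is None else a
        water[m] = w
        fatmap[m] = f

    # breathing-cycle table (deterministic from the master seed)
    rng = rng_for(config.seed, "resp-cycles")
    n_cyc = int(config.duration / config.resp_period * 1.5) + 4
    periods = np.maximum(rng.normal(config.resp_period, config.resp_period_sd, n_cyc),
                         0.5 * config.resp_period)
    amps = np.clip(rng.normal(1.0 - config.resp_amp_sd, config.resp_amp_sd, n_cyc),
                   0.6, 1.0)
    starts = np.concatenate([[0.0], np.cumsum(periods[:-1])])

    diaphragm_row = 0.32 * ny + 0.22 * ny  # inferior edge of the right lung
    apex_row = body_c[0] - body_s[0]
    return DynamicPhantom(
        config=config,
        labels=lab,
        activity=act,
        water=water,
        fat=fatmap,
        heart_center=heart_c,
        heart_radius=heart_r,
        diaphragm_row=diaphragm_row,
        apex_row=apex_row,
        fall_start=0.62 * ny,
        fall_end=0.96 * ny,
        resp_cycle_starts=starts,
        resp_cycle_periods=periods,
        resp_cycle_amps=amps,
    )


# ---------------------------------------------------------------------------
# deformation


def _invert_monotone(forward, grid):
    """Invert y' = forward(y) (monotone increasing) on a sampled grid."""
    fy = forward(grid)
    return lambda q: np.interp(q, fy, grid)


def motion_field(
    phantom: DynamicPhantom, resp_mm: float, cardiac_phase: float
) -> MotionGroundTruth:
    """Exact pull-back displacement field for the state ``(resp_mm,
    cardiac_phase)``; cardiac contraction acts innermost (in reference
    coordinates), respiration outermost."""
    cfg = phantom.config
    if not 0 <= resp_mm <= cfg.resp_amplitude + 1e-9:
        raise ValueError(f"resp_mm outside configured range [0, {cfg.resp_amplitude}]")
    if not 0 <= cardiac_phase < 1:
        raise ValueError("cardiac_phase must lie in [0, 1)")
    ny, nx = cfg.grid_shape
    px = cfg.pixel_size
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")

    # respiratory: rows move inferior by resp_mm * taper(row); invert rows
    if resp_mm > 0:
        a_px = resp_mm / px
        rows = np.linspace(-a_px - 2, ny + 1.0, 4 * ny)
        inv = _invert_monotone(lambda r: r + a_px * phantom.resp_taper(r), rows)
        ry = inv(yy[:, 0])[:, None] * np.ones((1, nx))
    else:
        ry = yy.copy()
    rx = xx.copy()

    # cardiac: radial contraction about the (reference) heart centre
    contr = cfg.cardiac_contraction_fraction * np.sin(np.pi * cardiac_phase) ** 2
    if contr > 0:
        cy, cx = phantom.heart_center
        r_t = phantom.heart_radius + 2.0  # taper support, px
        g = lambda rho: np.where(rho < r_t, np.cos(np.pi * rho / (2 * r_t)) ** 2, 0.0)
        rho_grid = np.linspace(0.0, r_t + 2.0, 4 * ny)
        inv_r = _invert_monotone(lambda r: r * (1 - contr * g(r)), rho_grid)
        dyc = ry - cy
        dxc = rx - cx
        rho = np.hypot(dyc, dxc)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rho > 1e-12, inv_r(rho) / np.maximum(rho, 1e-12), 1.0)
        inside = rho < r_t
        ry = np.where(inside, cy + dyc * scale, ry)
        rx = np.where(inside, cx + dxc * scale, rx)

    disp = np.stack([(ry - yy) * px, (rx - xx) * px])
    return MotionGroundTruth(disp=disp, resp_mm=resp_mm, cardiac_phase=cardiac_phase, pixel_size=px)


def deform(
    phantom: DynamicPhantom, resp_mm: float, cardiac_phase: float
) -> tuple[np.ndarray, np.ndarray, dict, MotionGroundTruth]:
    """Warp the reference phantom into the state ``(resp_mm, cardiac_phase)``.

    Returns ``(labels, activity, {"water": W, "fat": F}, ground_truth)``.
    Label maps use nearest-neighbour, continuous maps linear interpolation;
    the identity state returns the reference maps exactly.  The activity
    map is additionally weighted by the Jacobian determinant of the
    pull-back map so total activity (counts) is conserved when tissue
    stretches or compresses; MR signal maps are plain intensity warps.
    """
    gt = motion_field(phantom, resp_mm, cardiac_phase)
    if resp_mm == 0 and np.allclose(gt.disp, 0):
        return (
            phantom.labels.copy(),
            phantom.activity.copy(),
            {"water": phantom.water.copy(), "fat": phantom.fat.copy()},
            gt,
        )
    px = phantom.pixel_size
    lab = warp_image(phantom.labels.astype(float), gt.disp, px, order=0, cval=AIR).astype(np.int16)
    act = warp_image(phantom.activity, gt.disp, px, order=1)
    dyy, dyx = np.gradient(gt.disp[0] / px)
    dxy, dxx = np.gradient(gt.disp[1] / px)
    jac = (1.0 + dyy) * (1.0 + dxx) - dyx * dxy
    act = act * np.maximum(jac, 0.0)
    wat = warp_image(phantom.water, gt.disp, px, order=1)
    fat = warp_image(phantom.fat, gt.disp, px, order=1)
    return lab, np.maximum(act, 0.0), {"water": wat, "fat": fat}, gt


# ---------------------------------------------------------------------------
# surrogates


def generate_surrogates(config: PhantomConfig) -> SurrogateSet:
    """Belt, self-navigator and ECG R-peak surrogate signals for the full
    scan duration.  The belt lags the true diaphragm motion by
    ``belt_lag`` seconds; both traces carry additive Gaussian noise."""
    config.validate()
    if config.duration <= 10:
        raise PhantomConfigError("duration: must be > 10 s for surrogate generation")
    ph = build_phantom(config)
    rng = rng_for(config.seed, "surrogates")
    dt = 1.0 / config.surrogate_fs
    t = np.arange(0.0, config.duration, dt)
    d_true = ph.resp_waveform(t)

    belt = ph.resp_waveform(t - config.belt_lag)
    belt = belt + config.belt_noise_sd * config.resp_amplitude * rng.standard_normal(t.size)

    heart_taper = float(ph.resp_taper(np.array([ph.heart_center[0]]))[0])
    nav = heart_taper * d_true
    nav = nav + config.selfnav_noise_sd * config.resp_amplitude * rng.standard_normal(t.size)

    # R-peaks: cumulative normally distributed RR intervals
    n_est = int(config.duration / config.cardiac_rr_mean * 1.5) + 10
    rr = rng.normal(config.cardiac_rr_mean, config.cardiac_rr_sd, n_est)
    rr = np.maximum(rr, 0.3 * config.cardiac_rr_mean)
    peaks = np.cumsum(rr) + 0.2
    peaks = peaks[peaks < config.duration]

    return SurrogateSet(
        time=t,
        belt=belt,
        selfnav=nav,
        r_peaks=peaks,
        mr_window=(0.0, float(min(config.mr_window, config.duration))),
        fs=config.surrogate_fs,
        diaphragm_mm=d_true,
    )


def cardiac_phase(times: np.ndarray, r_peaks: np.ndarray) -> np.ndarray:
    """Cardiac phase in [0, 1) as the fraction of the current RR interval.

    Times before the first R-peak wrap around using the first RR interval;
    times after the last peak extend periodically with the last interval.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    pk = np.asarray(r_peaks, dtype=float)
    if pk.size < 2:
        raise ValueError("need at least two R-peaks")
    idx = np.searchsorted(pk, times, side="right") - 1
    rr_first = pk[1] - pk[0]
    rr_last = pk[-1] - pk[-2]
    phase = np.empty_like(times)
    before = idx < 0
    phase[before] = ((times[before] - pk[0]) % rr_first) / rr_first
    after = idx >= pk.size - 1
    phase[after] = ((times[after] - pk[-1]) % rr_last) / rr_last
    mid = ~(before | after)
    i = idx[mid]
    phase[mid] = (times[mid] - pk[i]) / (pk[i + 1] - pk[i])
    return np.clip(phase, 0.0, np.nextafter(1.0, 0.0))


def state_at(phantom: DynamicPhantom, surrogates: SurrogateSet, t: float) -> tuple[float, float]:
    """True motion state (resp displacement mm, cardiac phase) at time t."""
    resp = float(np.interp(t, surrogates.time, surrogates.diaphragm_mm))
    resp = min(resp, phantom.config.resp_amplitude)
    phase = float(cardiac_phase(np.array([t]), surrogates.r_peaks)[0])
    return resp, phase


def save_phantom(phantom: DynamicPhantom, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = phantom.pixel_size
    save_nifti(outdir / "labels.nii.gz", phantom.labels, px)
    save_nifti(outdir / "activity.nii.gz", phantom.activity, px)
    save_nifti(outdir / "water.nii.gz", phantom.water, px)
    save_nifti(outdir / "fat.nii.gz", phantom.fat, px)
    phantom.config.to_yaml(outdir / "phantom_config.yaml")
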