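"""Multi-echo Dixon MR acquisition of the moving phantom.

A 2D golden-angle radial trajectory stands in for the 3D radial
phase-encoding scheme of a thoracic Dixon scan: consecutive readouts rotate
by the golden angle so that any retrospectively selected subset of spokes
covers k-space quasi-uniformly, which is the property cardiorespiratory
binning relies on.

Signal model per echo ``e`` and k-space location ``k`` (single receive
coil, single-peak fat model, no B0 term):

    S_e(k) = sum_x [ W(x) + F(x) * exp(i 2 pi df TE_e) ] * exp(-i 2 pi k.x)

with ``df`` the fat chemical shift in Hz and ``W``, ``F`` the water/fat
maps of the phantom deformed to the motion state at the spoke timestamp.
Complex white Gaussian noise is added per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import phantom as ph
from ._utils import rng_for

GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0  # ~1.9416 rad ~ 111.246 deg


class MRConfigError(ValueError):
    pass


@dataclass
class MRSequenceConfig:
    tr: float = 7.57e-3  # s
    te: tuple[float, ...] = (2.62e-3, 4.13e-3, 5.64e-3)  # s
    flip_angle: float = 15.0  # deg, metadata only
    fat_shift_hz: float = -428.0
    noise_sd: float = 0.0  # relative to the reference DC magnitude
    spokes_total: int = 1500
    samples_per_spoke: int = 64
    # simulate every stride-th TR interval: the default spreads the default
    # 1500 spokes over the full 720 s MR window
    spoke_stride: int = 63
    readout_oversampling: float = 1.4  # radial kmax / axis Nyquist (<= sqrt 2)

    def validate(self) -> None:
        if len(self.te) < 2:
            raise MRConfigError("te: need at least two echoes")
        if np.any(np.diff(self.te) <= 0):
            raise MRConfigError("te: echo times must be strictly increasing")
        if self.tr <= 0:
            raise MRConfigError("tr: must be > 0")
        if self.spokes_total < 1 or self.samples_per_spoke < 2:
            raise MRConfigError("spokes_total/samples_per_spoke: too small")
        if self.spoke_stride < 1:
            raise MRConfigError("spoke_stride: must be >= 1")
        if not 1.0 <= self.readout_oversampling <= np.sqrt(2.0) + 1e-9:
            raise MRConfigError("readout_oversampling: must lie in [1, sqrt(2)]")

    @property
    def echo_phasors(self) -> np.ndarray:
        """exp(i 2 pi df TE_e) per echo."""
        return np.exp(2j * np.pi * self.fat_shift_hz * np.asarray(self.te))


@dataclass
class Trajectory:
    angles: np.ndarray  # rad, per spoke
    kappa: np.ndarray  # cycles/mm, per sample along any spoke
    times: np.ndarray  # s, per spoke

    @property
    def n_spokes(self) -> int:
        return self.angles.size


@dataclass
class KSpace:
    data: np.ndarray  # complex (n_echo, n_spokes, n_samples)
    trajectory: Trajectory
    config: MRSequenceConfig
    noise_sd_abs: float = 0.0


def make_trajectory(config: MRSequenceConfig, window: tuple[float, float],
                    pixel_size: float) -> Trajectory:
    """Golden-angle radial trajectory with TR-spaced timestamps.

    ``kappa`` spans [-Nyquist, Nyquist) of the given pixel size with
    ``samples_per_spoke`` readout points.
    """
    config.validate()
    t0, t1 = window
    if t1 <= t0:
        raise MRConfigError("window: length must be > 0")
    span = config.spokes_total * config.spoke_stride * config.tr
    if span > (t1 - t0) + 1e-9:
        raise MRConfigError(
            f"spokes_total: {config.spokes_total} spokes at stride "
            f"{config.spoke_stride} x TR {config.tr} s need {span:.2f} s, "
            f"exceeding the {t1 - t0:.2f} s acquisition window"
        )
    n = config.spokes_total
    angles = np.mod(np.arange(n) * GOLDEN_ANGLE, np.pi)
    m = config.samples_per_spoke
    # radial kmax reaches towards the corner Nyquist radius (sqrt2 x axis
    # Nyquist) so the Cartesian image spectrum is fully covered
    kappa = (np.arange(m) / m - 0.5) * config.readout_oversampling / pixel_size
    times = t0 + np.arange(n) * config.spoke_stride * config.tr
    return Trajectory(angles=angles, kappa=kappa, times=times)


# ---------------------------------------------------------------------------
# non-uniform Fourier encoding


class RadialEncoding:
    """Exact non-uniform DFT for a set of radial spokes.

    forward: image (ny, nx) -> samples (n_spokes * n_samples,);
    adjoint: exact conjugate transpose (same factorisation run backwards).

    Along a spoke the readout positions are uniformly spaced in k, so the
    sample matrix row m factorises as ``u_p * v_p^m`` per pixel p with
    ``u = exp(-2 pi i kappa_0 t)``, ``v = exp(-2 pi i d_kappa t)`` and
    ``t`` the pixel coordinate projected on the spoke direction.  Forward
    and adjoint are evaluated by the corresponding geometric recursion
    (Horner for the adjoint), which is exact and matrix-free.
    """

    def __init__(self, trajectory: Trajectory, spoke_idx, grid_shape,
                 pixel_size: float, cache_limit_bytes: float | None = None,
                 dtype=np.complex128):
        self.traj = trajectory
        self.spoke_idx = np.asarray(spoke_idx, dtype=int)
        self.grid_shape = tuple(grid_shape)
        self.pixel_size = float(pixel_size)
        self.dtype = np.dtype(dtype)
        ny, nx = self.grid_shape
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        ry = (yy * pixel_size).ravel()
        rx = (xx * pixel_size).ravel()
        self.n_samples = self.traj.kappa.size
        self.n_rows = self.spoke_idx.size * self.n_samples
        self.n_pix = ny * nx
        kap = self.traj.kappa
        dk = kap[1] - kap[0]
        th = self.traj.angles[self.spoke_idx]
        t = np.cos(th)[:, None] * ry[None, :] + np.sin(th)[:, None] * rx[None, :]
        self._u = np.exp((-2j * np.pi * kap[0]) * t).astype(self.dtype)
        self._v = np.exp((-2j * np.pi * dk) * t).astype(self.dtype)

    def _spoke_block(self, s: int) -> np.ndarray:
        """Dense sample matrix of one (trajectory-indexed) spoke."""
        ny, nx = self.grid_shape
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        ry = (yy * self.pixel_size).ravel()
        rx = (xx * self.pixel_size).ravel()
        th = self.traj.angles[s]
        t = np.cos(th) * ry + np.sin(th) * rx
        return np.exp((-2j * np.pi) * np.outer(self.traj.kappa, t)).astype(self.dtype)

    def forward(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image).ravel().astype(self.dtype)
        w = self._u * x[None, :]
        out = np.empty((self.spoke_idx.size, self.n_samples), dtype=self.dtype)
        for m in range(self.n_samples):
            out[:, m] = w.sum(axis=1)
            if m < self.n_samples - 1:
                w *= self._v
        return out.ravel()

    def forward_multi(self, images) -> np.ndarray:
        """Forward transform of several images at once; returns an array of
        shape (n_images, n_spokes * n_samples)."""
        xs = np.stack([np.asarray(im).ravel().astype(self.dtype) for im in images])
        w = self._u[None, :, :] * xs[:, None, :]
        out = np.empty((xs.shape[0], self.spoke_idx.size, self.n_samples), dtype=self.dtype)
        for m in range(self.n_samples):
            out[:, :, m] = w.sum(axis=2)
            if m < self.n_samples - 1:
                w *= self._v[None, :, :]
        return out.reshape(xs.shape[0], -1)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        return self.adjoint_multi(np.asarray(samples).ravel()[None, :])[0]

    def adjoint_multi(self, samples: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`forward_multi`; input (n_sets, n_rows)."""
        y = np.asarray(samples).astype(self.dtype)
        y = y.reshape(y.shape[0], self.spoke_idx.size, self.n_samples)
        vc = np.conj(self._v)[None, :, :]
        acc = np.zeros((y.shape[0], *self._u.shape), dtype=self.dtype)
        for m in range(self.n_samples - 1, -1, -1):
            acc *= vc
            acc += y[:, :, m][:, :, None]
        x = (np.conj(self._u)[None, :, :] * acc).sum(axis=1)
        return x.reshape(y.shape[0], *self.grid_shape)

    def forward_spoke(self, i: int, image: np.ndarray) -> np.ndarray:
        """Forward transform of one image restricted to local spoke i."""
        x = np.asarray(image).ravel().astype(self.dtype)
        w = self._u[i] * x
        out = np.empty(self.n_samples, dtype=self.dtype)
        for m in range(self.n_samples):
            out[m] = w.sum()
            if m < self.n_samples - 1:
                w *= self._v[i]
        return out


def simulate_acquisition(
    phan: ph.DynamicPhantom,
    surrogates: ph.SurrogateSet,
    config: MRSequenceConfig,
    trajectory: Trajectory,
    seed: int | None = None,
) -> KSpace:
    """Acquire multi-echo radial k-space of the moving phantom.

    Each spoke sees the phantom deformed to the true motion state at its
    timestamp; all echoes of a spoke share that state (the echo spacing is
    milliseconds, far below any physiological timescale).
    """
    config.validate()
    if trajectory.times[0] < surrogates.time[0] - 1e-9 or trajectory.times[-1] > surrogates.time[-1] + 1e-9:
        raise MRConfigError("trajectory timestamps fall outside the surrogate support")
    seed = phan.config.seed if seed is None else seed
    rng = rng_for(seed, "mr-noise")
    cfg = phan.config
    enc = RadialEncoding(trajectory, np.arange(trajectory.n_spokes), cfg.grid_shape,
                         cfg.pixel_size)
    phasors = config.echo_phasors
    n_e = phasors.size
    data = np.empty((n_e, trajectory.n_spokes, config.samples_per_spoke), dtype=np.complex128)

    dc_ref = abs(np.sum(phan.water + phan.fat))
    sd = config.noise_sd * dc_ref

    for s in range(trajectory.n_spokes):
        resp, phase = ph.state_at(phan, surrogates, float(trajectory.times[s]))
        _, _, maps, _ = ph.deform(phan, resp, phase)
        ew = enc.forward_spoke(s, maps["water"])
        ef = enc.forward_spoke(s, maps["fat"])
        for e in range(n_e):
            data[e, s] = ew + phasors[e] * ef
    if sd > 0:
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = data + sd * noise
    return KSpace(data=data, trajectory=trajectory, config=config, noise_sd_abs=float(sd))


def save_kspace(kspace: KSpace, path) -> None:
    """Persist as a .npz archive plus a YAML config snapshot alongside."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path,
        data=kspace.data,
        angles=kspace.trajectory.angles,
        kappa=kspace.trajectory.kappa,
        times=kspace.trajectory.times,
        noise_sd_abs=kspace.noise_sd_abs,
    )
    pd.DataFrame(
        {"angle_rad": kspace.trajectory.angles, "time_s": kspace.trajectory.times}
    ).to_csv(path.with_suffix(".spokes.csv"), index=False)
    cfg = kspace.config.__dict__.copy()
    cfg["te"] = list(kspace.config.te)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)
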