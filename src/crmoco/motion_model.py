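"""Non-rigid motion-model estimation from motion-resolved water/fat images.

The registration minimises the dual-channel cost

    C(m) = w * S(W_mov o m, W_fix) + (1 - w) * S(F_mov o m, F_fix) + r * R(m)

over a cubic B-spline-parameterised displacement field m, where S is
(negative) normalised mutual information or SSD, evaluated on image
magnitudes, and R is the bending energy of the field.  Water and fat enter
with equal weight by default (w = 0.5): the water channel carries the
myocardium/blood anatomy while the fat channel adds high-contrast
complementary edges, and the per-bin undersampling artefacts differ between
the two channels, so the second channel acts as extra regularisation.

Field convention (see ``crmoco._utils``): every stored field is a pull-back
field that warps the *reference* image into the bin's motion state — the
direction the MR encoding model, the attenuation-map warp and the PET MCIR
forward model all consume.  ``build_model`` therefore registers the
reference-bin image (moving) onto each bin image (fixed); the cost above is
symmetric in form, only the roles are mirrored.

Optimisation is multiresolution steepest descent with backtracking line
search on an analytically differentiated Parzen-window (linear kernel) NMI;
SSD mode provides a fast, exactly differentiable alternative for testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from ._utils import compose_fields, warp_image

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass
class RegistrationConfig:
    water_weight: float = 0.5  # w in [0, 1]
    reg_weight: float | None = None  # r; None -> 10%-of-initial-cost heuristic
    similarity: str = "nmi"  # "nmi" | "ssd"
    nmi_bins: int = 32
    control_spacing: float = 16.0  # mm
    levels: int = 3
    iterations: int = 60  # per level
    step0: float = 1.0  # initial step, mm
    tol: float = 1e-6  # relative cost-change stop criterion
    presmooth_sigma: float = 0.8  # px; regularises the Parzen-NMI surface
    snap_tol_px: float = 0.05  # fields below this max-magnitude snap to zero

    def validate(self, pixel_size: float) -> None:
        if not 0.0 <= self.water_weight <= 1.0:
            raise ValueError("water_weight must lie in [0, 1]")
        if self.reg_weight is not None and self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.control_spacing <= pixel_size:
            raise ValueError("control_spacing must exceed the pixel size")
        if self.similarity not in ("nmi", "ssd"):
            raise ValueError("similarity must be 'nmi' or 'ssd'")


@dataclass
class DisplacementField:
    disp: np.ndarray  # (2, ny, nx) mm, pull-back convention
    pixel_size: float

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.disp[0], self.disp[1])

    def warp(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        return warp_image(image, self.disp, self.pixel_size, order=order, cval=cval)


@dataclass
class RegistrationResult:
    field: DisplacementField
    cost: float
    sim_water: float
    sim_fat: float
    regulariser: float
    weights: tuple[float, float, float]  # (w, 1 - w, r)
    converged: bool


@dataclass
class MotionModel:
    fields: list[DisplacementField]
    reference: int
    motion_type: str  # respiratory | cardiac | cardiorespiratory
    thresholds: np.ndarray | None = None  # respiratory amplitude bin edges
    amplitude_range: tuple[float, float] | None = None
    time_shift: float = 0.0  # s, global belt shift
    n_resp: int | None = None
    n_card: int | None = None
    flags: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        ref = self.fields[self.reference]
        if not np.allclose(ref.disp, 0.0, atol=1e-9):
            raise ValueError("field at the reference bin must be identically zero")

    @property
    def n_bins(self) -> int:
        return len(self.fields)


# ---------------------------------------------------------------------------
# similarity metrics


def _rescale_pair(fixed: np.ndarray, moving: np.ndarray) -> tuple:
    """Joint 1st-99th percentile window shared by both images."""
    lo = min(np.percentile(fixed, 1), np.percentile(moving, 1))
    hi = max(np.percentile(fixed, 99), np.percentile(moving, 99))
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 1e-12]
    return float(-np.sum(nz * np.log(nz)))


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalised mutual information (H_a + H_b) / H_ab with a linear
    Parzen window on fixed-width bins over the joint 1-99% window."""
    lo, hi = _rescale_pair(a, b)
    ba = np.clip((a - lo) / (hi - lo) * (bins - 1), 0, bins - 1).ravel()
    bb = np.clip((b - lo) / (hi - lo) * (bins - 1), 0, bins - 1).ravel()
    hist = _joint_hist(ba, bb, bins)
    return _nmi_from_hist(hist)[0]


def _joint_hist(ba: np.ndarray, bb: np.ndarray, bins: int) -> np.ndarray:
    ia = np.minimum(np.floor(ba).astype(int), bins - 2)
    ib = np.minimum(np.floor(bb).astype(int), bins - 2)
    fa = ba - ia
    fb = bb - ib
    hist = np.zeros((bins, bins))
    for da, wa in ((0, 1 - fa), (1, fa)):
        for db, wb in ((0, 1 - fb), (1, fb)):
            np.add.at(hist, (ia + da, ib + db), wa * wb)
    return hist / ba.size


def _nmi_from_hist(p: np.ndarray):
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    hj = _entropy(p)
    ha = _entropy(pa)
    hb = _entropy(pb)
    if hj <= 1e-12:
        return 2.0, ha, hb, hj
    return (ha + hb) / hj, ha, hb, hj


def _nmi_and_grad(fixed_b: np.ndarray, moving_b: np.ndarray, bins: int):
    """NMI value and its gradient wrt the moving bin coordinates.

    ``fixed_b``/``moving_b`` are intensities already mapped to bin
    coordinates in [0, bins-1].  Returns (nmi, dnmi/dmoving_b per pixel).
    """
    n = fixed_b.size
    i_f = np.minimum(np.floor(fixed_b).astype(int), bins - 2)
    i_m = np.minimum(np.floor(moving_b).astype(int), bins - 2)
    f_f = fixed_b - i_f
    f_m = moving_b - i_m
    p = np.zeros((bins, bins))
    for df, wf in ((0, 1 - f_f), (1, f_f)):
        for dm, wm in ((0, 1 - f_m), (1, f_m)):
            np.add.at(p, (i_f + df, i_m + dm), wf * wm)
    p /= n
    val, ha, hb, hj = _nmi_from_hist(p)
    if hj <= 1e-12:
        return val, np.zeros_like(moving_b)
    pm = p.sum(axis=0)
    logp = np.where(p > 1e-12, np.log(np.maximum(p, 1e-300)), 0.0)
    logpm = np.where(pm > 1e-12, np.log(np.maximum(pm, 1e-300)), 0.0)
    # d n / d p_ij with n = (ha+hb)/hj:
    #   d ha/dp_ij = -(1+log pa_i), d hb/dp_ij = -(1+log pm_j),
    #   d hj/dp_ij = -(1+log p_ij); the -1 terms cancel in the quotient rule
    pa = p.sum(axis=1)
    logpa = np.where(pa > 1e-12, np.log(np.maximum(pa, 1e-300)), 0.0)
    dn_dp = (-(logpa[:, None] + logpm[None, :]) * hj + (ha + hb) * logp) / hj**2
    grad = np.zeros_like(moving_b)
    for df, wf in ((0, 1 - f_f), (1, f_f)):
        for dm, s in ((0, -1.0), (1, 1.0)):
            grad += dn_dp[i_f + df, i_m + dm] * wf * s
    return val, grad / n


# ---------------------------------------------------------------------------
# cubic B-spline field parameterisation (control grid fixed in physical mm)


def _bspline3(u: np.ndarray) -> np.ndarray:
    au = np.abs(u)
    out = np.zeros_like(au)
    m1 = au < 1
    out[m1] = 2.0 / 3.0 - au[m1] ** 2 + au[m1] ** 3 / 2.0
    m2 = (au >= 1) & (au < 2)
    out[m2] = (2.0 - au[m2]) ** 3 / 6.0
    return out


def _basis_matrix(coords_mm: np.ndarray, spacing: float, n_ctrl: int) -> np.ndarray:
    """Dense (n_points, n_ctrl) cubic B-spline basis; control point i sits
    at physical position (i - 1) * spacing."""
    u = coords_mm[:, None] / spacing - (np.arange(n_ctrl)[None, :] - 1)
    return _bspline3(u)


def _n_ctrl(extent_mm: float, spacing: float) -> int:
    return int(np.ceil(extent_mm / spacing)) + 3


def _bending(coef: np.ndarray, spacing: float):
    """Bending energy of the control lattice and its gradient."""
    r = 0.0
    grad = np.zeros_like(coef)
    s4 = spacing**4
    for c in range(2):
        cc = coef[c]
        dyy = cc[2:] - 2 * cc[1:-1] + cc[:-2]
        dxx = cc[:, 2:] - 2 * cc[:, 1:-1] + cc[:, :-2]
        dxy = cc[1:, 1:] - cc[1:, :-1] - cc[:-1, 1:] + cc[:-1, :-1]
        r += (np.sum(dyy**2) + np.sum(dxx**2) + 2 * np.sum(dxy**2)) / s4
        g = grad[c]
        g[2:] += 2 * dyy / s4
        g[1:-1] -= 4 * dyy / s4
        g[:-2] += 2 * dyy / s4
        g[:, 2:] += 2 * dxx / s4
        g[:, 1:-1] -= 4 * dxx / s4
        g[:, :-2] += 2 * dxx / s4
        g[1:, 1:] += 4 * dxy / s4
        g[1:, :-1] -= 4 * dxy / s4
        g[:-1, 1:] -= 4 * dxy / s4
        g[:-1, :-1] += 4 * dxy / s4
    n = coef[0].size
    return r / n, grad / n


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    ny, nx = (s - s % factor for s in img.shape)
    return sm[:ny, :nx].reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


class _Channel:
    """One similarity channel (water or fat magnitude) at one level."""

    def __init__(self, moving, fixed, bins, mode):
        self.moving = moving
        self.fixed = fixed
        self.mode = mode
        self.bins = bins
        self.degenerate = False
        if mode == "nmi":
            if np.ptp(fixed) < 1e-12 or np.ptp(moving) < 1e-12:
                self.degenerate = True
            else:
                lo, hi = _rescale_pair(fixed, moving)
                self.lo, self.hi = lo, hi
                self.fixed_b = np.clip((fixed - lo) / (hi - lo) * (bins - 1), 0, bins - 1)
        self.gy, self.gx = np.gradient(moving)

    def value_grad(self, coords, shape):
        """Similarity (to minimise) and its gradient wrt the warped moving
        intensities, plus the sampled moving-image spatial gradient."""
        mw = ndimage.map_coordinates(self.moving, coords, order=1, mode="nearest")
        gy = ndimage.map_coordinates(self.gy, coords, order=1, mode="nearest")
        gx = ndimage.map_coordinates(self.gx, coords, order=1, mode="nearest")
        if self.mode == "ssd":
            d = mw - self.fixed.ravel()
            val = float(np.mean(d**2))
            dval = 2 * d / d.size
        else:
            mb = np.clip((mw - self.lo) / (self.hi - self.lo) * (self.bins - 1), 0, self.bins - 1)
            v, g = _nmi_and_grad(self.fixed_b.ravel(), mb, self.bins)
            val = -v
            dval = -g * (self.bins - 1) / (self.hi - self.lo)
        return val, dval, gy, gx


def _extract_channels(img) -> tuple[np.ndarray, np.ndarray, float]:
    """Accept a WaterFatImage-like object, a (water, fat) pair or a plain
    array; complex channels enter as magnitudes."""
    if hasattr(img, "water"):
        w = np.abs(np.asarray(img.water))
        f = np.abs(np.asarray(img.fat))
        px = float(getattr(img, "pixel_size", 1.0))
    elif isinstance(img, tuple):
        w = np.abs(np.asarray(img[0]))
        f = np.abs(np.asarray(img[1]))
        px = 1.0
    else:
        w = np.abs(np.asarray(img))
        f = np.zeros_like(w)
        px = 1.0
    return w, f, px


def register_pair(moving, fixed, config: RegistrationConfig | None = None,
                  pixel_size: float | None = None) -> RegistrationResult:
    """Estimate the B-spline displacement field warping ``moving`` onto
    ``fixed`` by minimising the dual-channel cost."""
    config = config or RegistrationConfig()
    mw, mf, px_m = _extract_channels(moving)
    fw, ff, _ = _extract_channels(fixed)
    px = float(pixel_size or px_m)
    config.validate(px)
    if mw.shape != fw.shape:
        raise ValueError("moving and fixed images must share a grid")
    if config.presmooth_sigma > 0:
        mw, mf, fw, ff = (ndimage.gaussian_filter(a, config.presmooth_sigma)
                          for a in (mw, mf, fw, ff))
    ny, nx = mw.shape
    spacing = config.control_spacing
    ncy = _n_ctrl((ny - 1) * px, spacing)
    ncx = _n_ctrl((nx - 1) * px, spacing)
    coef = np.zeros((2, ncy, ncx))

    w = config.water_weight
    r_weight = config.reg_weight
    converged = False

    for level in range(config.levels):
        factor = 2 ** (config.levels - 1 - level)
        px_l = px * factor
        imgs = [_downsample(a, factor) for a in (mw, fw, mf, ff)]
        hly, hlx = imgs[0].shape
        offset = 0.5 * (px_l - px)  # block-mean pixel-centre shift
        ys = np.arange(hly) * px_l + offset
        xs = np.arange(hlx) * px_l + offset
        by = _basis_matrix(ys, spacing, ncy)
        bx = _basis_matrix(xs, spacing, ncx)
        chans = []
        weights = []
        for (mv, fx), cw in (((imgs[0], imgs[1]), w), ((imgs[2], imgs[3]), 1 - w)):
            ch = _Channel(mv, fx, config.nmi_bins, config.similarity)
            if ch.degenerate:
                warnings.warn(
                    "constant channel: NMI undefined, falling back to the other channel",
                    RuntimeWarning,
                )
                continue
            chans.append(ch)
            weights.append(cw)
        if not chans:
            raise ValueError("both channels are degenerate (constant images)")
        wsum = sum(weights)
        weights = [cw / wsum * 1.0 for cw in weights] if wsum > 0 else weights
        yy, xx = np.meshgrid(np.arange(hly, dtype=float), np.arange(hlx, dtype=float),
                             indexing="ij")

        def cost_terms(cf):
            uy = by @ cf[0] @ bx.T
            ux = by @ cf[1] @ bx.T
            coords = np.stack([(yy + uy / px_l).ravel(), (xx + ux / px_l).ravel()])
            svals, gacc = [], np.zeros((2, hly, hlx))
            for ch, cw in zip(chans, weights):
                val, dval, gy, gx = ch.value_grad(coords, (hly, hlx))
                svals.append(val)
                gacc[0] += cw * (dval * gy).reshape(hly, hlx) / px_l
                gacc[1] += cw * (dval * gx).reshape(hly, hlx) / px_l
            rval, rgrad = _bending(cf, spacing)
            return svals, rval, gacc, rgrad

        if r_weight is None:
            svals0, _, _, _ = cost_terms(coef)
            probe = np.zeros_like(coef)
            probe[:, ::2, ::2] = 1.0
            probe[:, 1::2, 1::2] = 1.0
            r_probe, _ = _bending(probe, spacing)
            s0 = abs(sum(cw * sv for cw, sv in zip(weights, svals0)))
            r_weight = 0.1 * max(s0, 1e-6) / max(r_probe, 1e-12)
            log.info("registration reg_weight heuristic: r = %.3g", r_weight)

        def total(cf):
            svals, rval, gacc, rgrad = cost_terms(cf)
            s = sum(cw * sv for cw, sv in zip(weights, svals))
            grad = np.zeros_like(cf)
            for c in range(2):
                grad[c] = by.T @ gacc[c] @ bx
            grad += r_weight * rgrad
            return s + r_weight * rval, svals, rval, grad

        from scipy.optimize import minimize

        shape_c = coef.shape

        def fun(z):
            c, _, _, g = total(z.reshape(shape_c))
            return c, g.ravel()

        opt = minimize(fun, coef.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": config.iterations,
                                "ftol": config.tol, "gtol": 1e-12})
        coef = opt.x.reshape(shape_c)
        cval, svals, rval, grad = total(coef)
        converged = bool(opt.success or opt.status == 1)

    # final dense field at full resolution
    ys = np.arange(ny) * px
    xs = np.arange(nx) * px
    by = _basis_matrix(ys, spacing, ncy)
    bx = _basis_matrix(xs, spacing, ncx)
    disp = np.stack([by @ coef[0] @ bx.T, by @ coef[1] @ bx.T])
    # book-keep final per-term values on the full-resolution cost
    sim_w = sim_f = 0.0
    if len(chans) == 2:
        sim_w, sim_f = svals
    elif chans:
        sim_w = sim_f = svals[0]
    cost_val = w * sim_w + (1 - w) * sim_f + r_weight * rval
    return RegistrationResult(
        field=DisplacementField(disp=disp, pixel_size=px),
        cost=float(cost_val),
        sim_water=float(sim_w),
        sim_fat=float(sim_f),
        regulariser=float(rval),
        weights=(w, 1 - w, float(r_weight)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# model assembly


def build_model(series, reference: int, config: RegistrationConfig | None = None,
                motion_type: str = "respiratory",
                thresholds: np.ndarray | None = None,
                amplitude_range: tuple[float, float] | None = None) -> MotionModel:
    """One displacement field per bin, zero at the reference bin.

    Registers the reference-bin image (moving) onto every other bin image
    (fixed) so each stored field warps the reference state into that bin.
    Bins flagged as empty inherit the field of the nearest non-empty bin.
    """
    if len(series) < 2:
        raise ValueError("need at least two bins to build a motion model")
    config = config or RegistrationConfig()
    _, _, px = _extract_channels(series[reference])
    nb = len(series)
    is_empty = [bool(getattr(img, "empty", False)) for img in series]
    if is_empty[reference]:
        raise ValueError("reference bin must not be empty")
    fields: list[DisplacementField | None] = [None] * nb
    flags = {}
    shape = _extract_channels(series[reference])[0].shape
    for b in range(nb):
        if b == reference:
            fields[b] = DisplacementField(np.zeros((2, *shape)), px)
            continue
        if is_empty[b]:
            continue
        res = register_pair(series[reference], series[b], config)
        f = res.field
        if np.max(np.abs(f.disp)) < config.snap_tol_px * f.pixel_size:
            f = DisplacementField(np.zeros_like(f.disp), f.pixel_size)
        fields[b] = f
    nonempty = [b for b in range(nb) if fields[b] is not None]
    for b in range(nb):
        if fields[b] is None:
            nearest = min(nonempty, key=lambda j: abs(j - b))
            fields[b] = DisplacementField(fields[nearest].disp.copy(), px)
            flags[b] = f"empty bin: field copied from bin {nearest}"
            log.warning("bin %d empty; copied field from bin %d", b, nearest)
    return MotionModel(
        fields=fields, reference=reference, motion_type=motion_type,
        thresholds=thresholds, amplitude_range=amplitude_range, flags=flags,
    )


def select_reference(belt_values: np.ndarray) -> str:
    """'end_exhale' or 'end_inhale', whichever half-range of the belt
    amplitude holds more samples (low belt = exhale; ties -> end_exhale)."""
    v = np.asarray(belt_values, dtype=float)
    if v.size == 0:
        raise ValueError("belt trace is empty")
    mid = 0.5 * (v.min() + v.max())
    n_low = int(np.sum(v < mid))
    n_high = int(np.sum(v > mid))
    if n_low == n_high:
        log.info("select_reference: exact tie, choosing end_exhale by convention")
        return "end_exhale"
    return "end_exhale" if n_low > n_high else "end_inhale"


def concatenate(resp: MotionModel, card: MotionModel,
                order: str = "cardiac-inner") -> MotionModel:
    """Cardiorespiratory model: one composed field per (resp, card) bin
    pair, indexed ``i_resp * n_card + i_card``.

    With the default order the cardiac transformation acts innermost (in
    reference coordinates) and respiration outermost, matching the pipeline
    order in which the models are estimated; the order is configurable.
    """
    f0 = resp.fields[0]
    if any(f.disp.shape != f0.disp.shape for f in card.fields):
        raise ValueError("respiratory and cardiac models must share a grid")
    px = f0.pixel_size
    fields = []
    for fr in resp.fields:
        for fc in card.fields:
            if order == "cardiac-inner":
                comp = compose_fields(fr.disp, fc.disp, px)
            else:
                comp = compose_fields(fc.disp, fr.disp, px)
            fields.append(DisplacementField(comp, px))
    nc = card.n_bins
    return MotionModel(
        fields=fields,
        reference=resp.reference * nc + card.reference,
        motion_type="cardiorespiratory",
        thresholds=resp.thresholds,
        amplitude_range=resp.amplitude_range,
        time_shift=resp.time_shift,
        n_resp=resp.n_bins,
        n_card=nc,
    )


# ---------------------------------------------------------------------------
# surrogate alignment and model extension


def align_belt(belt: np.ndarray, selfnav: np.ndarray, fs: float,
               max_shift: float) -> float:
    """Global time shift (s) of the belt maximising its normalised
    cross-correlation with the self-navigator.

    Returned shift ``s`` satisfies ``selfnav(t) ~ belt(t - s)``: apply the
    aligned belt by reading it at ``t - s``.
    """
    belt = np.asarray(belt, dtype=float)
    nav = np.asarray(selfnav, dtype=float)
    n = min(belt.size, nav.size)
    k_max = int(round(max_shift * fs))
    if k_max > n // 2:
        raise ValueError("shift search range exceeds half the signal overlap")
    b = belt[:n] - belt[:n].mean()
    v = nav[:n] - nav[:n].mean()
    best_k, best_r = 0, -np.inf
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            x, y = b[: n - k], v[k:]
        else:
            x, y = b[-k:], v[: n + k]
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        r = float(x @ y) / denom if denom > 0 else -np.inf
        # prefer the smallest |shift| among near-equal peaks (quasi-periodic
        # breathing yields correlation maxima one period apart)
        if r > best_r + 1e-9 or (r > best_r - 1e-9 and abs(k) < abs(best_k)):
            best_r, best_k = r, k
    return best_k / fs


def assign_bins(times: np.ndarray, belt_time: np.ndarray, belt: np.ndarray,
                shift: float, thresholds: np.ndarray,
                amplitude_range: tuple[float, float],
                r_peaks: np.ndarray, n_card: int):
    """Respiratory and cardiac bin index for arbitrary timestamps.

    Respiratory bins come from the stored amplitude thresholds applied to
    the shifted belt; amplitudes outside the range seen in the MR window
    are clamped to the edge bins and counted.  Cardiac bins use the ECG
    phase exactly as inside the window.

    Returns ``(resp_idx, card_idx, n_clamped)``.
    """
    from .phantom import cardiac_phase

    times = np.atleast_1d(np.asarray(times, dtype=float))
    vals = np.interp(times - shift, belt_time, belt)
    lo, hi = amplitude_range
    n_clamped = int(np.sum((vals < lo) | (vals > hi)))
    if n_clamped:
        log.info("assign_bins: %d samples outside the MR-window amplitude range (clamped)",
                 n_clamped)
    resp_idx = np.searchsorted(np.asarray(thresholds), vals, side="right")
    resp_idx = np.clip(resp_idx, 0, len(thresholds))
    card_idx = np.minimum((cardiac_phase(times, r_peaks) * n_card).astype(int), n_card - 1)
    return resp_idx, card_idx, n_clamped
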