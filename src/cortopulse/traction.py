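"""Traction force microscopy: bead displacement, FTTC inversion, RMS forces.

The substrate is an elastic half-space (Young's modulus ``E``, Poisson ratio
``nu``); surface displacement ``u`` and traction ``t`` are related in Fourier
space by the Boussinesq/Cerruti Green tensor::

    u_hat(k) = G_hat(k) t_hat(k)

    G_hat(k) = 2 (1 + nu) / (E k^3) * [[ (1-nu) k^2 + nu ky^2,  -nu kx ky ],
                                       [ -nu kx ky,  (1-nu) k^2 + nu kx^2 ]]

Fourier Transform Traction Cytometry inverts this relation with zeroth-order
Tikhonov regularization; the forward operator (used to synthesize bead
scenes) is the same kernel applied in the forward direction.  Real-space
check: a tangential point force F on the surface produces, along its own
axis, u = (1 + nu) F / (pi E r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.signal.windows import tukey
from scipy.interpolate import RegularGridInterpolator
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage.feature import match_template

from .types import ImageStack

__all__ = [
    "GelParams",
    "DisplacementField",
    "TractionField",
    "forward_displacement",
    "fttc",
    "rms_traction",
    "estimate_displacement",
    "estimate_noise_floor",
    "generate_bead_images",
    "choose_lambda_lcurve",
    "DEFAULT_LAMBDA",
]

# Tikhonov weight in (um/Pa)^2, picked at the L-curve corner of the noisy
# reference synthetic bead scene (see docs/methods.md); lambda = 0 disables
# regularization entirely.
DEFAULT_LAMBDA = 3.2e-11


@dataclass
class GelParams:
    """Elastic substrate: 26 kPa polyacrylamide, incompressible by default."""

    youngs_modulus_pa: float = 26000.0
    poisson_ratio: float = 0.5
    grid_spacing_um: float = 0.8

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5]")


@dataclass
class VectorGrid:
    """Vector field sampled on a regular grid; origin at the first node."""

    origin_um: tuple[float, float]
    spacing_um: float
    fx: np.ndarray  # (ny, nx) x-component
    fy: np.ndarray

    def __post_init__(self) -> None:
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        if self.fx.shape != self.fy.shape or self.fx.ndim != 2:
            raise ValueError("components must be matching 2D arrays")
        if self.spacing_um <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fx.shape

    def node_coords_um(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x = self.origin_um[0] + np.arange(nx) * self.spacing_um
        y = self.origin_um[1] + np.arange(ny) * self.spacing_um
        return x, y

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.fx, self.fy)


@dataclass
class DisplacementField(VectorGrid):
    """Surface displacement (µm) with per-vector PIV quality in [0, 1]."""

    quality: np.ndarray | None = None
    valid: np.ndarray | None = None
    noise_floor_um: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.quality is None:
            self.quality = np.ones(self.shape)
        if self.valid is None:
            self.valid = np.ones(self.shape, dtype=bool)

    @property
    def u(self) -> np.ndarray:
        return self.fx

    @property
    def v(self) -> np.ndarray:
        return self.fy


@dataclass
class TractionField(VectorGrid):
    """Surface traction (Pa); positive = substrate pulled toward the cell."""

    gel: GelParams = field(default_factory=GelParams)
    regularization_lambda: float = 0.0
    source_displacement: DisplacementField | None = None

    @property
    def tx(self) -> np.ndarray:
        return self.fx

    @property
    def ty(self) -> np.ndarray:
        return self.fy


def _greens_tensor_ft(kx: np.ndarray, ky: np.ndarray, gel: GelParams):
    """Boussinesq surface Green tensor in Fourier space (µm/Pa)."""
    E, nu = gel.youngs_modulus_pa, gel.poisson_ratio
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        g11 = pref * ((1.0 - nu) * k2 + nu * ky**2)
        g12 = pref * (-nu * kx * ky)
        g22 = pref * ((1.0 - nu) * k2 + nu * kx**2)
    zero = k2 == 0
    for g in (g11, g12, g22):
        g[zero] = 0.0
    return g11, g12, g22


def _padded_fft_setup(shape: tuple[int, int], spacing_um: float, pad_factor: float):
    ny, nx = shape
    py = next_fast_len(int(math.ceil(ny * pad_factor)))
    px = next_fast_len(int(math.ceil(nx * pad_factor)))
    ky = 2.0 * np.pi * np.fft.fftfreq(py, d=spacing_um)
    kx = 2.0 * np.pi * np.fft.fftfreq(px, d=spacing_um)
    return (py, px), np.meshgrid(kx, ky)


def _taper_pad(a: np.ndarray, py: int, px: int) -> np.ndarray:
    """Pad to (py, px) with a raised-cosine blend that is circularly smooth.

    The pad band interpolates from the last row/column back to the first so
    the periodic continuation seen by the FFT has no step at either edge of
    the data block.
    """
    ny, nx = a.shape
    ramp_x = px - nx
    if ramp_x > 0:
        wx = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, ramp_x + 1) / (ramp_x + 1)))
        band = a[:, -1][:, None] * wx[None, :] + a[:, 0][:, None] * (1.0 - wx[None, :])
        a = np.concatenate([a, band], axis=1)
    ramp_y = py - ny
    if ramp_y > 0:
        wy = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, ramp_y + 1) / (ramp_y + 1)))
        band = a[-1, :][None, :] * wy[:, None] + a[0, :][None, :] * (1.0 - wy[:, None])
        a = np.concatenate([a, band], axis=0)
    return a


def forward_displacement(
    traction: TractionField, pad_factor: float = 2.0
) -> DisplacementField:
    """Surface displacement of the half-space under a traction field.

    The field is zero-padded to at least ``pad_factor`` times its extent to
    suppress periodic wrap-around; the operator is linear in the traction
    and inversely proportional to the Young's modulus.
    """
    ny, nx = traction.shape
    (py, px), (KX, KY) = _padded_fft_setup(
        (ny, nx), traction.spacing_um, pad_factor
    )
    tx = np.zeros((py, px))
    ty = np.zeros((py, px))
    tx[:ny, :nx] = traction.fx
    ty[:ny, :nx] = traction.fy
    g11, g12, g22 = _greens_tensor_ft(KX, KY, traction.gel)
    tx_hat, ty_hat = fft2(tx), fft2(ty)
    u = np.real(ifft2(g11 * tx_hat + g12 * ty_hat))[:ny, :nx]
    v = np.real(ifft2(g12 * tx_hat + g22 * ty_hat))[:ny, :nx]
    return DisplacementField(traction.origin_um, traction.spacing_um, u, v)


def fttc(
    displacement: DisplacementField,
    gel: GelParams,
    regularization_lambda: float = DEFAULT_LAMBDA,
    pad_factor: float = 2.0,
    edge_taper: float = 0.0,
) -> TractionField:
    """Fourier Transform Traction Cytometry.

    Mean displacement is subtracted (the absolute substrate offset is not
    observable), the field is zero-padded to at least twice its extent, and
    the traction spectrum is recovered with zeroth-order Tikhonov
    regularization::

        t_hat = (G^T G + lambda I)^{-1} G^T u_hat

    ``regularization_lambda`` has units (µm/Pa)²; 0 is permitted and gives
    the plain inverse kernel.  ``edge_taper`` is the Tukey fraction applied
    to the mean-subtracted field before the transform: the inverse kernel is
    a high-pass operator, so an unwindowed crop edge rings across the whole
    reconstruction.
    """
    if regularization_lambda < 0:
        raise ValueError("lambda must be >= 0")
    if not (np.all(np.isfinite(displacement.fx)) and np.all(np.isfinite(displacement.fy))):
        raise ValueError("displacement contains NaN; impute invalid vectors first")
    ny, nx = displacement.shape
    u = displacement.fx - displacement.fx.mean()
    v = displacement.fy - displacement.fy.mean()
    if edge_taper > 0:
        win = np.outer(tukey(ny, edge_taper), tukey(nx, edge_taper))
        u = u * win
        v = v * win
    (py, px), (KX, KY) = _padded_fft_setup((ny, nx), displacement.spacing_um, pad_factor)
    # taper the measured field to zero across the pad band: a hard zero step
    # at the crop edge would be amplified by the (high-pass) inverse kernel
    up = _taper_pad(u, py, px)
    vp = _taper_pad(v, py, px)
    g11, g12, g22 = _greens_tensor_ft(KX, KY, gel)
    u_hat, v_hat = fft2(up), fft2(vp)
    lam = regularization_lambda
    # per-k 2x2 solve of (G^T G + lam I) t = G^T u   (G symmetric real)
    a11 = g11 * g11 + g12 * g12 + lam
    a12 = g12 * (g11 + g22)
    a22 = g12 * g12 + g22 * g22 + lam
    b1 = g11 * u_hat + g12 * v_hat
    b2 = g12 * u_hat + g22 * v_hat
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        tx_hat = (a22 * b1 - a12 * b2) / det
        ty_hat = (a11 * b2 - a12 * b1) / det
    zero = (KX**2 + KY**2) == 0
    tx_hat[zero] = 0.0
    ty_hat[zero] = 0.0
    tx = np.real(ifft2(tx_hat))[:ny, :nx]
    ty = np.real(ifft2(ty_hat))[:ny, :nx]
    return TractionField(
        displacement.origin_um,
        displacement.spacing_um,
        tx,
        ty,
        gel=gel,
        regularization_lambda=lam,
        source_displacement=displacement,
    )


def rms_traction(
    traction: TractionField, roi_polygon_um
) -> tuple[float, bool]:
    """RMS traction magnitude over the grid nodes inside an ROI polygon.

    ``below_floor_flag`` is set when the ROI's mean displacement does not
    exceed the displacement noise floor (forces too weak to resolve).
    """
    poly = (
        roi_polygon_um
        if isinstance(roi_polygon_um, Polygon)
        else Polygon(roi_polygon_um)
    )
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate ROI polygon")
    x, y = traction.node_coords_um()
    XX, YY = np.meshgrid(x, y)
    inside = contains_xy(poly, XX.ravel(), YY.ravel()).reshape(XX.shape)
    if not inside.any():
        raise ValueError("ROI polygon does not intersect the traction grid")
    mag2 = traction.fx[inside] ** 2 + traction.fy[inside] ** 2
    rms = float(np.sqrt(mag2.mean()))
    disp = traction.source_displacement
    if disp is not None:
        mean_disp = float(disp.magnitude()[inside].mean())
        flag = mean_disp <= disp.noise_floor_um
    else:
        flag = rms == 0.0
    return rms, flag


# ---------------------------------------------------------------------------
# PIV


def _gauss3_offset(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation along one axis."""
    if cm <= 0 or c0 <= 0 or cp <= 0:
        denom = cm - 2.0 * c0 + cp  # parabolic fallback
        return 0.0 if denom == 0 else float(0.5 * (cm - cp) / denom)
    lm, l0, lp = math.log(cm), math.log(c0), math.log(cp)
    denom = 2.0 * (lm + lp - 2.0 * l0)
    return 0.0 if denom == 0 else float((lm - lp) / denom)


def estimate_displacement(
    stressed: ImageStack | np.ndarray,
    reference: ImageStack | np.ndarray,
    window_px: int = 32,
    overlap: float = 0.5,
    search_margin_px: int | None = None,
    quality_threshold: float = 0.3,
    min_contrast: float = 0.05,
    pixel_size_um: float | None = None,
) -> DisplacementField:
    """Bead displacement by windowed normalized cross-correlation.

    Each reference window is matched inside a padded search region of the
    stressed frame; the NCC peak is refined with three-point Gaussian
    interpolation (skipped when the match is numerically perfect, in which
    case the shift is exactly integral).  Windows whose standard deviation
    falls below ``min_contrast`` times the reference image's (no beads — the
    correlation surface is flat and meaningless) are flagged invalid and,
    together with low-quality vectors, replaced by the local median of
    their neighbors.
    """
    if isinstance(stressed, ImageStack):
        px_um = stressed.pixel_size_um
        stressed = stressed.data[0] if stressed.data.ndim == 3 else stressed.data
    else:
        px_um = pixel_size_um if pixel_size_um is not None else 1.0
        stressed = np.asarray(stressed, dtype=float)
    if isinstance(reference, ImageStack):
        reference = reference.data[0] if reference.data.ndim == 3 else reference.data
    else:
        reference = np.asarray(reference, dtype=float)
    if stressed.shape != reference.shape:
        raise ValueError("images must have the same shape")
    if window_px < 16:
        raise ValueError("window must be at least 16 px")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    margin = window_px // 2 if search_margin_px is None else search_margin_px
    step = max(int(round(window_px * (1.0 - overlap))), 1)
    h, w = reference.shape

    rows = np.arange(0, h - window_px + 1, step)
    cols = np.arange(0, w - window_px + 1, step)
    ny, nx = len(rows), len(cols)
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    quality = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)

    contrast_floor = max(min_contrast * reference.std(), 1e-12)
    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            tmpl = reference[r0 : r0 + window_px, c0 : c0 + window_px]
            if tmpl.std() < contrast_floor:
                continue  # featureless: flagged invalid
            rs, re = max(r0 - margin, 0), min(r0 + window_px + margin, h)
            cs, ce = max(c0 - margin, 0), min(c0 + window_px + margin, w)
            region = stressed[rs:re, cs:ce]
            ncc = match_template(region, tmpl, pad_input=False)
            pk = np.unravel_index(np.argmax(ncc), ncc.shape)
            c_peak = float(ncc[pk])
            dy = pk[0] + rs - r0
            dx = pk[1] + cs - c0
            if c_peak < 1.0 - 1e-9:
                py, px_ = pk
                if 0 < py < ncc.shape[0] - 1:
                    dy += _gauss3_offset(ncc[py - 1, px_], c_peak, ncc[py + 1, px_])
                if 0 < px_ < ncc.shape[1] - 1:
                    dx += _gauss3_offset(ncc[py, px_ - 1], c_peak, ncc[py, px_ + 1])
            u[i, j] = dx * px_um
            v[i, j] = dy * px_um
            quality[i, j] = max(c_peak, 0.0)
            valid[i, j] = True

    # impute invalid / low-quality vectors with the local median
    bad = ~valid | (quality < quality_threshold)
    if bad.any() and (~bad).any():
        for i, j in zip(*np.nonzero(bad)):
            i0, i1 = max(i - 1, 0), min(i + 2, ny)
            j0, j1 = max(j - 1, 0), min(j + 2, nx)
            nb = ~bad[i0:i1, j0:j1]
            if nb.any():
                u[i, j] = np.median(u[i0:i1, j0:j1][nb])
                v[i, j] = np.median(v[i0:i1, j0:j1][nb])
    valid &= ~bad

    origin = (
        (cols[0] + window_px / 2.0) * px_um,
        (rows[0] + window_px / 2.0) * px_um,
    )
    return DisplacementField(
        origin_um=origin,
        spacing_um=step * px_um,
        fx=u,
        fy=v,
        quality=quality,
        valid=valid,
    )


def estimate_noise_floor(field: DisplacementField, mask: np.ndarray | None = None) -> float:
    """RMS displacement magnitude over a cell-free region (or everywhere)."""
    mag = field.magnitude()
    if mask is not None:
        mag = mag[mask]
    return float(np.sqrt(np.mean(mag**2)))


def choose_lambda_lcurve(
    displacement: DisplacementField,
    gel: GelParams,
    lambdas: np.ndarray | None = None,
) -> float:
    """Pick the Tikhonov weight at the L-curve corner.

    Scans candidate lambdas, records residual norm ``|G t - u|`` versus
    solution norm ``|t|``, and returns the lambda of maximum curvature in
    log-log coordinates.
    """
    if lambdas is None:
        lambdas = np.logspace(-12, -4, 17)
    res, sol = [], []
    for lam in lambdas:
        t = fttc(displacement, gel, regularization_lambda=float(lam))
        ufwd = forward_displacement(t)
        res.append(
            np.sqrt(
                np.mean(
                    (ufwd.fx - (displacement.fx - displacement.fx.mean())) ** 2
                    + (ufwd.fy - (displacement.fy - displacement.fy.mean())) ** 2
                )
            )
        )
        sol.append(np.sqrt(np.mean(t.fx**2 + t.fy**2)))
    lr, ls = np.log(np.asarray(res) + 1e-300), np.log(np.asarray(sol) + 1e-300)
    # curvature of the parametric curve (lr(lam), ls(lam))
    t_par = np.log(lambdas)
    dr, ds = np.gradient(lr, t_par), np.gradient(ls, t_par)
    d2r, d2s = np.gradient(dr, t_par), np.gradient(ds, t_par)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dr * d2s - ds * d2r) / (dr**2 + ds**2) ** 1.5
    kappa[~np.isfinite(kappa)] = -np.inf
    return float(lambdas[int(np.argmax(kappa))])


# ---------------------------------------------------------------------------
# synthetic bead scenes (forward model)


def generate_bead_images(
    tractions: TractionField,
    gel: GelParams | None = None,
    bead_density_per_um2: float = 0.08,
    bead_sigma_um: float = 0.2,
    pixel_size_um: float = 0.2,
    amplitude: float = 100.0,
    baseline: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, DisplacementField]:
    """Render a (reference, stressed) bead image pair from a traction field.

    Beads are isotropic Gaussian spots (default sigma matching 0.2 µm
    microspheres); the stressed frame shifts each spot center by the
    forward-computed surface displacement interpolated at the bead position,
    keeping the ground truth exact.  Returns the reference frame, the
    stressed frame, and the ground-truth displacement on the traction grid.
    """
    if bead_sigma_um <= 0:
        raise ValueError("bead_sigma_um must be positive")
    gel = gel or tractions.gel
    ratio = tractions.spacing_um / pixel_size_um
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            "traction grid spacing must be an integer multiple of the pixel size"
        )
    disp = forward_displacement(tractions)
    gx, gy = tractions.node_coords_um()
    interp_u = RegularGridInterpolator(
        (gy, gx), disp.fx, bounds_error=False, fill_value=0.0
    )
    interp_v = RegularGridInterpolator(
        (gy, gx), disp.fy, bounds_error=False, fill_value=0.0
    )

    width = gx[-1] + tractions.spacing_um
    height = gy[-1] + tractions.spacing_um
    nx = int(round(width / pixel_size_um))
    ny = int(round(height / pixel_size_um))
    rng = np.random.default_rng(seed)
    n_beads = rng.poisson(bead_density_per_um2 * width * height)
    pos = rng.random((n_beads, 2)) * (width, height)
    shift = np.column_stack(
        [interp_u(pos[:, ::-1]), interp_v(pos[:, ::-1])]
    )

    def render(centers: np.ndarray) -> np.ndarray:
        img = np.full((ny, nx), baseline, dtype=float)
        half = int(math.ceil(4.0 * bead_sigma_um / pixel_size_um))
        for cx, cy in centers:
            jc, ic = int(cx / pixel_size_um), int(cy / pixel_size_um)
            j0, j1 = max(jc - half, 0), min(jc + half + 1, nx)
            i0, i1 = max(ic - half, 0), min(ic + half + 1, ny)
            if j0 >= j1 or i0 >= i1:
                continue
            xs = (np.arange(j0, j1) + 0.5) * pixel_size_um - cx
            ys = (np.arange(i0, i1) + 0.5) * pixel_size_um - cy
            img[i0:i1, j0:j1] += amplitude * np.exp(
                -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * bead_sigma_um**2)
            )
        return img

    ref = render(pos)
    stressed = render(pos + shift)
    if noise_sd > 0:
        ref = ref + rng.normal(0.0, noise_sd, ref.shape)
        stressed = stressed + rng.normal(0.0, noise_sd, stressed.shape)
    return (
        ImageStack(ref, pixel_size_um),
        ImageStack(stressed, pixel_size_um),
        disp,
    )
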