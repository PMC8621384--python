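"""Multiscale Hessian vesselness (2D Jerman filter).

The filter enhances elongated structures from the eigenvalues of the
scale-normalized Hessian.  In 2D, writing |λ1| ≤ |λ2| for the eigenvalues
at scale σ, a vessel cross-section produces one large positive eigenvalue
λ2 (after polarity adjustment) and a near-zero λ1.  The response is a
ratio-based function of λ2 and a regularized copy λρ of it:

    λρ = λ2                    if λ2 > τ·max_x λ2(x, σ)
       = τ·max_x λ2(x, σ)      if 0 < λ2 ≤ τ·max_x λ2(x, σ)
       = 0                     otherwise

    ν  = 0                                   if λ2 ≤ 0 or λρ ≤ 0
       = 1                                   if λ2 ≥ λρ/2 > 0
       = λ2²·(λρ − λ2)·(3/(λ2 + λρ))³        otherwise

ν is continuous (the cubic branch equals 1 at λ2 = λρ/2), bounded by 1,
and plateaus at 1 inside vessels whose radius matches the scale.  The
final map is the pointwise supremum of ν over a span of scales.

The cut-off τ ∈ (0, 1] trades uniformity for selectivity: low τ lifts the
response of faint, thin vessels toward the plateau (preserving
connectivity), high τ keeps only the strongest ridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = [
    "JermanParams",
    "HessianField",
    "EigenField",
    "VesselnessMap",
    "hessian_at_scale",
    "eigenvalues_2x2",
    "regularize_lambda",
    "jerman_response",
    "vesselness",
]

DARK_ON_BRIGHT = "dark-on-bright"
BRIGHT_ON_DARK = "bright-on-dark"


@dataclass
class JermanParams:
    """Parameters of the multiscale vesselness filter.

    tau
        Cut-off threshold of the eigenvalue regularization, in (0, 1].
        Default 0.5 — the low end, which best preserves vessel
        connectivity.
    s_min, s_max, s_step
        Scale span, expressed as the probed vessel width (diameter) in
        pixels; defaults 3..16 step 0.5.  Each printed scale s maps to a
        Gaussian derivative kernel of σ = s/4 (γ = 2, i.e. σ²
        normalization), so the response of a vessel of width s peaks
        near scale s.  Scales far above every structure in the image are
        counterproductive: the per-scale regularization then amplifies
        whatever weak curvature remains, flooding the background.
    polarity
        ``"dark-on-bright"`` (fundus vessels in the green channel) or
        ``"bright-on-dark"``.
    """

    tau: float = 0.5
    s_min: float = 3.0
    s_max: float = 16.0
    s_step: float = 0.5
    polarity: str = DARK_ON_BRIGHT

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        if not (0.0 < self.s_min <= self.s_max):
            raise ValueError("require 0 < s_min <= s_max")
        if self.s_step <= 0:
            raise ValueError("s_step must be positive")
        if self.polarity not in (DARK_ON_BRIGHT, BRIGHT_ON_DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def scales(self) -> np.ndarray:
        """The printed scale grid (probed vessel widths, pixels)."""
        return np.arange(self.s_min, self.s_max + self.s_step / 2, self.s_step)

    @property
    def sigmas(self) -> np.ndarray:
        """Gaussian σ per scale: σ = s/4."""
        return self.scales / 4.0


@dataclass
class HessianField:
    """Scale-normalized second derivatives at one scale (hxy stored once)."""

    hxx: np.ndarray
    hxy: np.ndarray
    hyy: np.ndarray
    scale: float


@dataclass
class EigenField:
    """Per-pixel eigenvalues with |lam1| <= |lam2|."""

    lam1: np.ndarray
    lam2: np.ndarray


@dataclass
class VesselnessMap:
    """Multiscale filter response in [0, 1]."""

    response: np.ndarray
    params: JermanParams
    per_scale: Optional[Dict[float, np.ndarray]] = field(default=None)


def hessian_at_scale(img: np.ndarray, sigma: float) -> HessianField:
    """σ²-normalized Hessian: Gaussian smoothing + central differences.

    All steps are separable convolutions with reflect padding; x is the
    column coordinate and y the row.  Smoothing followed by exact central
    difference stencils ([1, −2, 1] and the cross stencil) reproduces the
    continuum Hessian exactly on quadratics (a sampled quadratic stays a
    quadratic under smoothing, and second differences of quadratics are
    exact), which keeps the scale normalization interpretable.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("hessian_at_scale expects a 2D image")
    if not np.isfinite(img).all():
        raise ValueError("image must be finite")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    # truncate=4.0 (scipy default): kernel radius 4σ must fit in the image
    if int(4.0 * sigma + 0.5) >= min(img.shape):
        raise DegenerateInputError(
            f"sigma={sigma} kernel exceeds image extent {img.shape}"
        )
    s2 = sigma * sigma
    sm = ndimage.gaussian_filter(img, sigma, mode="reflect")
    d2 = np.array([1.0, -2.0, 1.0])
    d1 = np.array([0.5, 0.0, -0.5])
    hxx = ndimage.correlate1d(sm, d2, axis=1, mode="reflect") * s2
    hyy = ndimage.correlate1d(sm, d2, axis=0, mode="reflect") * s2
    hxy = ndimage.correlate1d(
        ndimage.correlate1d(sm, d1, axis=0, mode="reflect"),
        d1, axis=1, mode="reflect",
    ) * s2
    return HessianField(hxx=hxx, hxy=hxy, hyy=hyy, scale=sigma)


def eigenvalues_2x2(h: HessianField) -> EigenField:
    """Closed-form eigenvalues of [[hxx, hxy], [hxy, hyy]] per pixel.

    Ordered |lam1| <= |lam2|; equal-magnitude ties are ordered ascending
    by signed value.
    """
    half_tr = 0.5 * (h.hxx + h.hyy)
    half_diff = 0.5 * (h.hxx - h.hyy)
    disc = np.sqrt(half_diff * half_diff + h.hxy * h.hxy)
    lo = half_tr - disc  # signed ascending
    hi = half_tr + disc
    swap = np.abs(lo) > np.abs(hi)
    lam1 = np.where(swap, hi, lo)
    lam2 = np.where(swap, lo, hi)
    return EigenField(lam1=lam1, lam2=lam2)


def regularize_lambda(lam2: np.ndarray, tau: float) -> np.ndarray:
    """Cut-off regularization of λ2 against its per-scale maximum."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    lam2 = np.asarray(lam2, dtype=np.float64)
    m = float(lam2.max()) if lam2.size else 0.0
    if m <= 0.0:
        return np.zeros_like(lam2)
    cut = tau * m
    out = np.where(lam2 > cut, lam2, np.where(lam2 > 0.0, cut, 0.0))
    return out


def jerman_response(lam2, lam_rho):
    """Pointwise ratio-based enhancement function, in [0, 1].

    Accepts scalars or arrays (broadcast)."""
    lam2 = np.asarray(lam2, dtype=np.float64)
    lam_rho = np.asarray(lam_rho, dtype=np.float64)
    scalar = lam2.ndim == 0 and lam_rho.ndim == 0
    lam2, lam_rho = np.broadcast_arrays(lam2, lam_rho)
    out = np.zeros(lam2.shape, dtype=np.float64)
    pos = (lam2 > 0.0) & (lam_rho > 0.0)
    plateau = pos & (lam2 >= lam_rho / 2.0)
    out[plateau] = 1.0
    body = pos & ~plateau
    if body.any():
        l2 = lam2[body]
        lr = lam_rho[body]
        out[body] = l2 * l2 * (lr - l2) * (3.0 / (l2 + lr)) ** 3
    return float(out[()]) if scalar else out


def vesselness(img: np.ndarray, p: Optional[JermanParams] = None) -> VesselnessMap:
    """Multiscale vesselness: supremum of the per-scale response.

    Per scale: σ²-normalized Hessian → closed-form eigenvalues → polarity
    sign adjustment → per-scale regularization of λ2 → pointwise response.
    Dark-on-bright tubes give positive cross-sectional curvature directly;
    bright-on-dark negates both eigenvalues first.
    """
    if p is None:
        p = JermanParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("vesselness expects a 2D image")
    response = np.zeros_like(img)
    per_scale: Dict[float, np.ndarray] = {}
    sign = 1.0 if p.polarity == DARK_ON_BRIGHT else -1.0
    for sigma in p.sigmas:
        h = hessian_at_scale(img, float(sigma))
        eig = eigenvalues_2x2(h)
        lam2 = sign * eig.lam2
        lam_rho = regularize_lambda(lam2, p.tau)
        resp = jerman_response(lam2, lam_rho)
        per_scale[float(sigma)] = resp
        np.maximum(response, resp, out=response)
    return VesselnessMap(response=response, params=p, per_scale=per_scale)
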