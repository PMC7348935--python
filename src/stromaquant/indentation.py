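"""Spherical nano-indentation: load–displacement → stress/strain → modulus.

A displacement-controlled nano-indenter drives a spherical probe (radius R)
on a cantilever of stiffness k into a soft sample and records piezo
displacement z and load P.  The true indentation depth is

    h = (z − z_contact) − P/k,

piezo travel past the contact point minus the cantilever deflection.  The
record is converted to an indentation stress/strain pair built on the
Hertzian contact radius a = √(R·h):

    σ_ind = P / (π a²),      ε_ind = (4 / 3π) · (h / a) / (1 − ν²),

definitions chosen so that for an ideal Hertzian material the ratio σ/ε is
the elastic modulus E at every depth — equivalently, σ_ind is linear in
ε_ind with slope E, and the slope of a zero-intercept least-squares fit is
the reported modulus.  Substituting a = √(Rh) shows σ/ε reduces exactly to
the classical Hertz relation P = (4/3)·E/(1−ν²)·√R·h^{3/2}.

All computations are performed in SI units; the public containers carry
instrument-convention units (µm, N, N/m) and are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class IndentationCurve:
    """One loading segment of a spherical indentation record.

    displacement_um : piezo displacement, µm, monotone non-decreasing
    load_n          : measured load, N
    tip_radius_um   : probe radius R, µm
    cantilever_stiffness : k, N/m
    poisson_ratio   : ν of the sample, in [0, 0.5]
    """

    displacement_um: np.ndarray
    load_n: np.ndarray
    tip_radius_um: float
    cantilever_stiffness: float
    poisson_ratio: float = 0.5
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_um = np.asarray(self.displacement_um, dtype=np.float64)
        self.load_n = np.asarray(self.load_n, dtype=np.float64)
        if self.displacement_um.shape != self.load_n.shape:
            raise ValueError("displacement and load must have the same length")
        if self.displacement_um.size < 10:
            raise ValueError("need at least 10 samples")
        if self.tip_radius_um <= 0 or self.cantilever_stiffness <= 0:
            raise ValueError("tip radius and cantilever stiffness must be positive")
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass
class ContactPoint:
    index: int            # first sample at or past contact
    z_offset_um: float    # piezo reading at the contact point
    fallback: bool = False


def detect_contact_point(
    curve: IndentationCurve,
    noise_multiplier: float = 5.0,
    baseline_fraction: float = 0.05,
    smooth_window: int = 7,
) -> ContactPoint:
    """Locate the contact point from the pre-contact load baseline.

    The baseline mean and SD are estimated from the first
    ``baseline_fraction`` of samples; the rise is where the smoothed load
    first exceeds mean + noise_multiplier·SD.  That crossing is
    systematically late (the load is already above the noise band there),
    so it is back-extrapolated to zero load using the Hertzian geometry:
    with u = z − P/k the deflection-corrected travel, P^{2/3} is exactly
    linear in u past contact, and the root of a least-squares line through
    (u, P^{2/3}) over the clearly-above-noise samples is the contact
    offset.  If the crossing already falls inside the baseline window (no
    usable pre-contact region) the first sample is used and a warning is
    issued.  A record whose load never rises above the baseline band
    raises — there is no contact to find.
    """
    P = curve.load_n
    z = curve.displacement_um
    n = P.size
    n_base = max(5, int(round(baseline_fraction * n)))
    # a clear monotone load trend inside the baseline window means the
    # record starts at (or past) contact and has no usable baseline
    bslope, bicept = np.polyfit(np.arange(n_base, dtype=float), P[:n_base], 1)
    bresid = float(np.std(P[:n_base] - (bslope * np.arange(n_base) + bicept)))
    if abs(bslope) * (n_base - 1) > 5.0 * bresid and bslope * (n_base - 1) > 0:
        warnings.warn(
            "no pre-contact baseline (load rises from the first sample); "
            "using the first sample as the contact point",
            stacklevel=2,
        )
        return ContactPoint(index=0, z_offset_um=float(z[0]), fallback=True)
    base_mean = float(P[:n_base].mean())
    base_sd = float(P[:n_base].std(ddof=1))
    threshold = base_mean + noise_multiplier * base_sd

    w = min(smooth_window, n)
    smooth = np.convolve(P, np.ones(w) / w, mode="same")
    above = smooth > threshold
    # demand a sustained crossing: the final smoothed load must clear the
    # band too, otherwise a stray noise spike would pass for contact
    if not above.any() or smooth[-w:].mean() <= threshold:
        raise ValueError("no contact detected: load never rises above the baseline")
    idx = int(np.argmax(above))
    if idx <= n_base:
        warnings.warn(
            "contact falls inside the baseline window; using the first sample",
            stacklevel=2,
        )
        return ContactPoint(index=0, z_offset_um=float(z[0]), fallback=True)

    # Hertz-consistent back-extrapolation on the raw loads
    net = P - base_mean
    sel = net > max(noise_multiplier * base_sd, 0.0)
    sel[: idx - 1] = False
    u = z[sel] - net[sel] / curve.cantilever_stiffness * 1e6
    y = net[sel] ** (2.0 / 3.0)
    z0 = float(z[idx - 1])  # fallback: last sample before the crossing
    if y.size >= 2:
        slope, intercept = np.polyfit(u, y, 1)
        if slope > 0:
            # contact cannot lie past the first clearly-loaded sample
            z0 = float(np.clip(-intercept / slope, z[0], u[0]))
    return ContactPoint(index=idx, z_offset_um=z0)


def correct_cantilever(
    curve: IndentationCurve, contact: ContactPoint
) -> tuple[np.ndarray, np.ndarray]:
    """True indentation depth per post-contact sample.

    h = (z − z_contact) − P/k.  Samples with h ≤ 0 belong to the
    pre-contact region and are excluded.  Returns (h_um, load_n) over the
    retained samples.
    """
    z_m = curve.displacement_um * 1e-6
    z0_m = contact.z_offset_um * 1e-6
    h_m = (z_m - z0_m) - curve.load_n / curve.cantilever_stiffness
    keep = h_m > 0
    if not keep.any():
        raise ValueError(
            "no positive indentation depth after cantilever correction "
            "(stiffness too small for these loads?)"
        )
    return h_m[keep] * 1e6, curve.load_n[keep]


@dataclass
class StressStrainRecord:
    """Per-sample indentation stress/strain derived from (P, h)."""

    depth_um: np.ndarray
    contact_radius_um: np.ndarray  # a = √(R·h)
    stress_pa: np.ndarray          # σ_ind = P / (π a²)
    strain: np.ndarray             # ε_ind = (4/3π)·(h/a)/(1−ν²)


def stress_strain(
    load_n: np.ndarray,
    depth_um: np.ndarray,
    tip_radius_um: float,
    poisson_ratio: float = 0.5,
) -> StressStrainRecord:
    """Map (P, h) to indentation stress and strain; h = 0 points are dropped."""
    P = np.asarray(load_n, dtype=np.float64)
    h_m = np.asarray(depth_um, dtype=np.float64) * 1e-6
    keep = h_m > 0
    P, h_m = P[keep], h_m[keep]
    R_m = tip_radius_um * 1e-6
    a_m = np.sqrt(R_m * h_m)
    sigma = P / (np.pi * a_m ** 2)
    eps = (4.0 / (3.0 * np.pi)) * (h_m / a_m) / (1.0 - poisson_ratio ** 2)
    return StressStrainRecord(
        depth_um=h_m * 1e6,
        contact_radius_um=a_m * 1e6,
        stress_pa=sigma,
        strain=eps,
    )


@dataclass
class ModulusFit:
    """Elastic modulus from the σ–ε relation of one indentation record.

    For an incompressible sample (ν = 0.5) the fitted E equals (1−ν²)·E*
    of the reduced modulus E*; both readings are retained in ``E_pa`` and
    ``reduced_modulus_pa``.
    """

    E_pa: float
    reduced_modulus_pa: float
    residual_norm: float
    contact_index: int
    depth_range_um: tuple[float, float]
    pointwise_mean_pa: float
    pointwise_sd_pa: float
    intercept: float = 0.0  # forced


def elastic_modulus(
    curve: IndentationCurve,
    fit_depth_range_um: tuple[float, float] | None = None,
    noise_multiplier: float = 5.0,
    min_depth_fraction: float = 0.1,
) -> ModulusFit:
    """Full record → modulus: contact detection, cantilever correction, σ–ε fit.

    E is the slope of the zero-intercept least-squares fit of σ_ind against
    ε_ind over the fit range.  By default the shallowest 10% of the depth
    record is excluded — there the relative error of the detected contact
    point dominates h.  The pointwise ratio σ/ε is also aggregated and
    reported as mean ± SD.
    """
    contact = detect_contact_point(curve, noise_multiplier=noise_multiplier)
    h_um, P = correct_cantilever(curve, contact)
    if fit_depth_range_um is None:
        fit_depth_range_um = (min_depth_fraction * float(h_um.max()),
                              float(h_um.max()))
    lo, hi = fit_depth_range_um
    sel = (h_um >= lo) & (h_um <= hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 post-contact samples in the fit range")
    ss = stress_strain(P[sel], h_um[sel], curve.tip_radius_um, curve.poisson_ratio)

    denom = float(ss.strain @ ss.strain)
    slope = float(ss.stress_pa @ ss.strain) / denom
    if slope <= 0:
        raise ValueError("non-positive σ–ε slope: no meaningful modulus")
    resid = float(np.linalg.norm(ss.stress_pa - slope * ss.strain))
    ratio = ss.stress_pa / ss.strain
    return ModulusFit(
        E_pa=slope,
        reduced_modulus_pa=slope / (1.0 - curve.poisson_ratio ** 2),
        residual_norm=resid,
        contact_index=contact.index,
        depth_range_um=(float(ss.depth_um.min()), float(ss.depth_um.max())),
        pointwise_mean_pa=float(ratio.mean()),
        pointwise_sd_pa=float(ratio.std(ddof=1)) if ratio.size > 1 else 0.0,
    )


def sample_modulus(fits) -> dict[str, float | int | None]:
    """Aggregate replicate indentation fits (e.g. 5 points per sample).

    ``fits`` may contain ModulusFit objects, raw moduli in Pa, or None for
    failed indentations.  Returns mean ± SD over the successes along with
    the failure count; raises if every fit failed.
    """
    values = []
    n_failed = 0
    for f in fits:
        if f is None:
            n_failed += 1
        elif isinstance(f, ModulusFit):
            values.append(f.E_pa)
        else:
            values.append(float(f))
    if not values:
        raise ValueError("all indentation fits failed")
    arr = np.asarray(values)
    return {
        "mean_pa": float(arr.mean()),
        "sd_pa": float(arr.std(ddof=1)) if arr.size > 1 else None,
        "n": int(arr.size),
        "n_failed": n_failed,
    }
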