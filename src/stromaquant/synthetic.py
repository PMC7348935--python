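"""Synthetic inputs with known ground truth.

Every generator here is a pure function of its spec, including the seed:
the same spec yields a bit-identical artifact on every call.  The ground
truth travels with the object (``CalibratedImage.ground_truth`` or an extra
return value) so downstream stages can be validated by direct, independent
computation.

Generators
----------
make_fiber_image
    Straight-line fibers with Gaussian cross-sections; stands in for SHG
    collagen images.  Real collagen fibers are curvilinear; straight
    segments are enough to control thickness and orientation disorder.
make_correlated_field
    Stationary Gaussian random field with exponential spatial covariance of
    a prescribed correlation length, synthesized spectrally.
make_nuclei_image
    Non-overlapping bright disks on a dark background (a DAPI channel
    stand-in) with an exact object count.
make_indentation_curve
    Hertzian spherical-indentation load–displacement record, including
    pre-contact travel and cantilever deflection.
make_deg_fixture
    A pair of differential-expression tables constructed so that the
    concordance partition recovers prescribed category sizes exactly.
make_count_matrix
    Negative-binomial RNA-seq style count matrix with per-gene
    multi-mapping-read percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CalibratedImage


# ---------------------------------------------------------------------------
# fiber images


@dataclass(frozen=True)
class FiberImageSpec:
    """Parameters of a straight-fiber network image.

    ``fiber_width`` is the sigma of the Gaussian cross-section profile in
    pixels.  ``orientation_concentration`` is the von Mises κ of the fiber
    angle distribution: 0 gives isotropic ("chaotic") networks, large values
    give aligned ones.
    """

    image_size: int = 512
    n_fibers: int = 40
    fiber_width: float = 2.0
    orientation_concentration: float = 0.0
    intensity: float = 1.0
    background_noise_sd: float = 0.0
    pixel_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.fiber_width <= 0:
            raise ValueError("fiber_width must be positive")


def make_fiber_image(spec: FiberImageSpec) -> CalibratedImage:
    """Render a fiber-network image plus its ground-truth fiber mask.

    Each fiber is an infinite straight line through a uniformly random
    center, at an angle drawn from a von Mises distribution (κ = 0 means
    uniform).  Its intensity profile is ``intensity * exp(-d² / 2σ²)`` in
    the perpendicular distance ``d``.  The ground-truth mask marks pixels
    whose *noiseless* summed fiber intensity exceeds half the single-fiber
    peak intensity; the mask and the noiseless image are stored in
    ``ground_truth``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    clean = np.zeros((n, n), dtype=np.float64)

    for _ in range(spec.n_fibers):
        cy, cx = rng.uniform(0, n, size=2)
        if spec.orientation_concentration > 0:
            theta = rng.vonmises(0.0, spec.orientation_concentration)
        else:
            theta = rng.uniform(-math.pi, math.pi)
        # signed perpendicular distance to the line through (cy, cx) at angle theta
        ny_, nx_ = -math.sin(theta), math.cos(theta)
        dist = (cols - cx) * ny_ - (rows - cy) * nx_
        clean += spec.intensity * np.exp(-(dist ** 2) / (2.0 * spec.fiber_width ** 2))

    mask = clean > 0.5 * spec.intensity
    noisy = clean
    if spec.background_noise_sd > 0:
        noisy = clean + rng.normal(0.0, spec.background_noise_sd, size=clean.shape)
        noisy = np.clip(noisy, 0.0, None)
    return CalibratedImage(
        noisy,
        pixel_size=spec.pixel_size,
        ground_truth={
            "fiber_mask": mask,
            "clean": clean,
            "mask_fraction_pct": 100.0 * mask.sum() / mask.size,
            "spec": spec,
        },
    )


# ---------------------------------------------------------------------------
# correlated random fields


@dataclass(frozen=True)
class FieldSpec:
    """A stationary Gaussian field with exponential covariance exp(-d/λ₀)."""

    image_size: int = 1024
    target_corr_length: float = 20.0
    pixel_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.target_corr_length <= 0:
            raise ValueError("target_corr_length must be positive")


def make_correlated_field(spec: FieldSpec) -> CalibratedImage:
    """Spectrally synthesize an exponential-covariance Gaussian field.

    The 2D isotropic exponential covariance exp(-r/λ) has radial spectral
    density S(k) ∝ λ² (1 + (kλ)²)^{-3/2} (the Matérn family at ν = 1/2).
    White Gaussian noise is filtered in Fourier space by √S, which gives a
    stationary periodic field whose covariance approximates the target on
    scales well below the grid size.  The field is affinely rescaled to
    [0, 1]; GLCM correlation is invariant to that rescaling.
    """
    spec.validate()
    if spec.target_corr_length >= spec.image_size / 2:
        import warnings

        warnings.warn(
            "target_corr_length is not resolvable on this grid "
            f"(λ₀={spec.target_corr_length} ≥ image_size/2)",
            stacklevel=2,
        )
    n = spec.image_size
    lam = spec.target_corr_length
    rng = np.random.default_rng(spec.seed)

    fx = np.fft.fftfreq(n)  # cycles / px
    k2 = (2.0 * math.pi) ** 2 * (fx[None, :] ** 2 + fx[:, None] ** 2)
    spectrum = lam ** 2 * (1.0 + k2 * lam ** 2) ** -1.5
    noise = rng.standard_normal((n, n))
    f = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spectrum)).real

    lo, hi = f.min(), f.max()
    f = (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)
    return CalibratedImage(
        f,
        pixel_size=spec.pixel_size,
        ground_truth={"target_corr_length": lam, "spec": spec},
    )


# ---------------------------------------------------------------------------
# nuclei images


def make_nuclei_image(
    n: int,
    radius_range: tuple[float, float] = (5.0, 8.0),
    image_size: int = 512,
    pixel_size: float = 1.0,
    intensity: float = 1.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> CalibratedImage:
    """Place ``n`` non-overlapping bright disks by rejection sampling.

    Raises ``RuntimeError`` if the requested configuration cannot be placed
    within ``max_tries`` proposals — never silently fewer disks.  The true
    count, centers and radii are stored in ``ground_truth``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rmin, rmax = radius_range
    if not (0 < rmin <= rmax):
        raise ValueError("radius_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} disjoint disks in a {image_size}² image "
                f"after {max_tries} proposals (placed {len(centers)})"
            )
        tries += 1
        r = rng.uniform(rmin, rmax)
        cy = rng.uniform(r, image_size - r)
        cx = rng.uniform(r, image_size - r)
        # keep a 1 px guard band so disks stay disjoint after rasterization
        if all(
            math.hypot(cy - py, cx - px) > r + pr + 1.0
            for (py, px), pr in zip(centers, radii)
        ):
            centers.append((cy, cx))
            radii.append(r)

    rows, cols = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    img = np.zeros((image_size, image_size), dtype=np.float64)
    for (cy, cx), r in zip(centers, radii):
        img[(rows - cy) ** 2 + (cols - cx) ** 2 <= r ** 2] = intensity
    return CalibratedImage(
        img,
        pixel_size=pixel_size,
        ground_truth={"count": n, "centers": centers, "radii": radii},
    )


def make_disk_image(
    radius: float,
    image_size: int = 512,
    pixel_size: float = 1.0,
    intensity: float = 1.0,
) -> CalibratedImage:
    """A single centred filled disk (micro-tissue optical image stand-in)."""
    c = (image_size - 1) / 2.0
    rows, cols = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    img = np.where((rows - c) ** 2 + (cols - c) ** 2 <= radius ** 2, intensity, 0.0)
    return CalibratedImage(
        img, pixel_size=pixel_size, ground_truth={"radius_px": radius}
    )


# ---------------------------------------------------------------------------
# indentation curves


@dataclass(frozen=True)
class IndentationSpec:
    """Ground-truth parameters of a spherical nano-indentation record.

    Units follow instrument conventions: depths and radii in µm, loads in N,
    cantilever stiffness in N/m.  ``load_noise_sd`` is the additive Gaussian
    noise sigma as a fraction of the maximum load; ``contact_offset`` is the
    zero-load piezo travel before the probe touches the surface.
    """

    true_modulus: float = 1000.0       # Pa
    poisson_ratio: float = 0.5
    tip_radius: float = 53.5           # µm
    max_depth: float = 10.0            # µm
    cantilever_stiffness: float = 4.53  # N/m
    load_noise_sd: float = 0.0
    contact_offset: float = 2.0        # µm
    n_samples: int = 600
    seed: int = 0

    def validate(self) -> None:
        if self.true_modulus <= 0:
            raise ValueError("true_modulus must be positive")
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")
        if self.tip_radius <= 0 or self.cantilever_stiffness <= 0:
            raise ValueError("tip_radius and cantilever_stiffness must be positive")
        if self.contact_offset < 0:
            raise ValueError("contact_offset must be >= 0")


def hertz_load(h_um: float | np.ndarray, E: float, nu: float, R_um: float) -> np.ndarray:
    """Hertz load P = (4/3)·E/(1-ν²)·√R·h^{3/2} in newtons (h, R in µm)."""
    h = np.asarray(h_um, dtype=np.float64) * 1e-6
    R = R_um * 1e-6
    return (4.0 / 3.0) * (E / (1.0 - nu ** 2)) * np.sqrt(R) * h ** 1.5


def make_indentation_curve(spec: IndentationSpec):
    """Simulate a displacement-controlled spherical indentation record.

    The true indentation depth ``h`` runs 0 → max_depth; piezo displacement
    is ``z = contact_offset + h + P/k`` (sample indentation plus cantilever
    deflection).  Pre-contact samples cover the zero-load approach.  Returns
    an :class:`~stromaquant.indentation.IndentationCurve` whose
    ``ground_truth`` holds the spec and the exact contact offset.
    """
    from .indentation import IndentationCurve

    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # sample count split so the z-axis sampling density is roughly uniform
    approx_span = spec.contact_offset + spec.max_depth
    n_pre = int(round(spec.n_samples * spec.contact_offset / approx_span)) if approx_span > 0 else 0
    n_post = spec.n_samples - n_pre
    if n_post < 10:
        raise ValueError("n_samples too small for the post-contact segment")

    h = np.linspace(0.0, spec.max_depth, n_post)
    P_post = hertz_load(h, spec.true_modulus, spec.poisson_ratio, spec.tip_radius)
    deflection_um = P_post / spec.cantilever_stiffness * 1e6
    z_post = spec.contact_offset + h + deflection_um
    z_pre = (
        np.linspace(0.0, spec.contact_offset, n_pre, endpoint=False)
        if n_pre > 0
        else np.empty(0)
    )
    z = np.concatenate([z_pre, z_post])
    P = np.concatenate([np.zeros(n_pre), P_post])
    if spec.load_noise_sd > 0:
        P = P + rng.normal(0.0, spec.load_noise_sd * P_post.max(), size=P.size)

    return IndentationCurve(
        displacement_um=z,
        load_n=P,
        tip_radius_um=spec.tip_radius,
        cantilever_stiffness=spec.cantilever_stiffness,
        poisson_ratio=spec.poisson_ratio,
        ground_truth={"spec": spec, "contact_offset_um": spec.contact_offset,
                      "true_depth_um": h},
    )


# ---------------------------------------------------------------------------
# DEG fixtures


#: category keys of a two-contrast concordance fixture, in a fixed order
DEG_CATEGORIES = (
    "a_up", "a_down", "b_up", "b_down",
    "common_up", "common_down", "discordant", "unchanged",
)


@dataclass(frozen=True)
class DEGFixtureSpec:
    """Category sizes and value ranges for a paired DEG-table fixture.

    ``category_sizes`` maps the keys of :data:`DEG_CATEGORIES` to counts
    (missing keys default to 0).  FDR values for significant calls are drawn
    inside ``fdr_significant_range`` and for null calls inside
    ``fdr_null_range``; both must sit on one side of the 0.05 significance
    threshold so the ground-truth partition is unambiguous.
    """

    category_sizes: dict = field(default_factory=dict)
    fdr_significant_range: tuple[float, float] = (1e-6, 0.01)
    fdr_null_range: tuple[float, float] = (0.2, 0.99)
    logfc_magnitude_range: tuple[float, float] = (0.5, 6.0)
    seed: int = 0

    def validate(self) -> None:
        for key in self.category_sizes:
            if key not in DEG_CATEGORIES:
                raise ValueError(f"unknown category {key!r}")
            if self.category_sizes[key] < 0:
                raise ValueError("category sizes must be >= 0")
        lo, hi = self.fdr_significant_range
        if not (0 <= lo <= hi < 0.05):
            raise ValueError(
                "fdr_significant_range must lie strictly below the 0.05 threshold"
            )
        lo, hi = self.fdr_null_range
        if not (0.05 <= lo <= hi <= 1.0):
            raise ValueError("fdr_null_range must lie at or above the 0.05 threshold")
        lo, hi = self.logfc_magnitude_range
        if not (0 < lo <= hi):
            raise ValueError("logfc_magnitude_range must be positive")


def make_deg_fixture(spec: DEGFixtureSpec):
    """Build two DEG tables whose concordance partition is known exactly.

    Returns ``(table_a, table_b, truth)`` where the tables are DataFrames
    with columns (gene, logFC, FDR) over a shared synthetic gene universe
    and ``truth`` maps each category to its gene-id set.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = {k: int(spec.category_sizes.get(k, 0)) for k in DEG_CATEGORIES}
    total = sum(sizes.values())
    genes = np.array([f"GENE{i:06d}" for i in range(total)])

    def draw_fdr(k: int, significant: bool) -> np.ndarray:
        lo, hi = spec.fdr_significant_range if significant else spec.fdr_null_range
        return rng.uniform(lo, hi, size=k)

    def draw_lfc(k: int, sign: int) -> np.ndarray:
        lo, hi = spec.logfc_magnitude_range
        return sign * rng.uniform(lo, hi, size=k)

    rows_a, rows_b, truth = [], [], {k: set() for k in DEG_CATEGORIES}
    pos = 0
    # per-category (significant_in_A, sign_A, significant_in_B, sign_B)
    plan = {
        "a_up": (True, +1, False, 0),
        "a_down": (True, -1, False, 0),
        "b_up": (False, 0, True, +1),
        "b_down": (False, 0, True, -1),
        "common_up": (True, +1, True, +1),
        "common_down": (True, -1, True, -1),
        "discordant": (True, +1, True, -1),
        "unchanged": (False, 0, False, 0),
    }
    for cat in DEG_CATEGORIES:
        k = sizes[cat]
        ids = genes[pos : pos + k]
        pos += k
        truth[cat] = set(ids)
        sig_a, sign_a, sig_b, sign_b = plan[cat]
        # null genes get a small random logFC of arbitrary sign
        lfc_a = draw_lfc(k, sign_a) if sig_a else rng.uniform(-0.4, 0.4, size=k)
        lfc_b = draw_lfc(k, sign_b) if sig_b else rng.uniform(-0.4, 0.4, size=k)
        if cat == "discordant" and k > 0:
            # half the discordant genes flip direction (up in B, down in A)
            flip = rng.random(k) < 0.5
            lfc_a[flip] *= -1
            lfc_b[flip] *= -1
        rows_a.append(pd.DataFrame({"gene": ids, "logFC": lfc_a,
                                    "FDR": draw_fdr(k, sig_a)}))
        rows_b.append(pd.DataFrame({"gene": ids, "logFC": lfc_b,
                                    "FDR": draw_fdr(k, sig_b)}))

    table_a = pd.concat(rows_a, ignore_index=True)
    table_b = pd.concat(rows_b, ignore_index=True)
    # shuffle row order so nothing downstream can rely on block structure
    order = rng.permutation(total)
    table_a = table_a.iloc[order].reset_index(drop=True)
    table_b = table_b.iloc[order].reset_index(drop=True)
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# count matrices


def make_count_matrix(
    n_genes: int = 2000,
    n_samples: int = 4,
    dispersion: float = 0.1,
    mean_range: tuple[float, float] = (0.0, 500.0),
    perc_mm_range: tuple[float, float] = (0.0, 60.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix with a per-gene ``perc_MM`` column.

    Per-gene means are drawn log-uniformly across ``mean_range`` (genes with
    mean 0 stay exactly zero), counts are NB with the given dispersion
    (variance µ + µ²·dispersion), and each gene carries a multi-mapping-read
    percentage drawn uniformly from ``perc_mm_range``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = mean_range
    if hi <= 0:
        means = np.zeros(n_genes)
    else:
        means = np.exp(rng.uniform(np.log(max(lo, 1e-2)), np.log(max(hi, 1e-2)),
                                   size=n_genes))
        if lo <= 0:  # a fraction of genes are silent
            means[rng.random(n_genes) < 0.1] = 0.0
    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    nz = means > 0
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + means[nz])
        counts[nz] = rng.negative_binomial(r, p[:, None], size=(nz.sum(), n_samples))
    else:
        counts[nz] = rng.poisson(means[nz][:, None], size=(nz.sum(), n_samples))
    df = pd.DataFrame(
        counts,
        index=[f"GENE{i:06d}" for i in range(n_genes)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )
    df["perc_MM"] = rng.uniform(*perc_mm_range, size=n_genes)
    return df
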