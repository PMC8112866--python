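"""Synthetic fluorescence-microscopy data with known ground truth.

This module generates the four kinds of data the analysis stages consume,
each with the statistical structure the downstream estimators assume:

* **DSLB TIRF fields** (:func:`simulate_dslb_field`): a planar supported
  bilayer carrying single fluorophores, trimers (emitters of exactly three
  molecules) and clusters whose molecule counts follow a lognormal law
  truncated below a minimum size. Emitters are rendered with an isotropic
  2-D Gaussian PSF integrated analytically over pixel areas and truncated
  at five sigma.
* **GUV equatorial sections** (:func:`simulate_guv_set`): giant unilamellar
  vesicles appear as bright rings in the membrane channel; protein clusters
  appear as punctate discs on the ring in the protein channel, with the
  number of clusters per liposome drawn from a Poisson law.
* **Two-channel colocalization pairs** (:func:`simulate_coloc_pair`): puncta
  in channel B co-positioned with channel A puncta at a controlled fraction.
* **FRAP traces** (:func:`simulate_frap_trace`): single-exponential recovery
  towards a plateau set by the mobile fraction.

Every generator takes an explicit integer seed and is bit-reproducible:
identical parameters and seed give identical output. There is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .core import ImageField, ParameterError, SizingError
from .frap import FRAPTrace

__all__ = [
    "FieldSimParams",
    "GUVSimParams",
    "ColocSimParams",
    "FRAPSimParams",
    "EmitterTruth",
    "GUVTruth",
    "ColocTruth",
    "simulate_dslb_field",
    "simulate_guv_set",
    "simulate_coloc_pair",
    "simulate_frap_trace",
    "sample_cluster_molecule_counts",
]

_NOISE_MODELS = ("none", "poisson", "gaussian", "poisson_gaussian")
_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSimParams:
    """Parameters for a simulated DSLB TIRF field.

    Intensity units are arbitrary detector units (ADU); the integrated
    intensity of one fluorophore is drawn per emitter from a normal law with
    mean ``single_intensity_mean`` and coefficient of variation
    ``single_intensity_cv``. Cluster molecule counts follow
    ``lognormal(cluster_logmu, cluster_logsigma)`` with draws below
    ``cluster_min_molecules`` redrawn; the default law has median 25 and
    arithmetic mean 38 molecules, matching a high-cholesterol bilayer.
    A cluster's molecules are placed in a disc of radius
    ``cluster_packing_um * sqrt(n_molecules)`` so areal density is constant.
    """

    seed: int
    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    single_intensity_mean: float = 1000.0
    single_intensity_cv: float = 0.1
    psf_sigma_px: float = 1.3
    background_level: float = 100.0
    noise_model: str = "poisson_gaussian"
    gaussian_noise_sd: float = 10.0
    n_singles: int = 0
    n_trimers: int = 0
    n_clusters: int = 0
    cluster_logmu: float = math.log(25.0)
    cluster_logsigma: float = math.sqrt(2.0 * math.log(38.0 / 25.0))
    cluster_min_molecules: int = 11
    cluster_packing_um: float = 0.05
    cluster_fixed_molecules: Optional[int] = None

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 32 or w < 32:
            raise ParameterError("field_size_px must be at least 32 on each side")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        if not (self.single_intensity_mean > 0):
            raise ParameterError("single_intensity_mean must be positive")
        if not (0 <= self.single_intensity_cv < 1):
            raise ParameterError("single_intensity_cv must lie in [0, 1)")
        if not (self.psf_sigma_px > 0):
            raise ParameterError("psf_sigma_px must be positive")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ParameterError("background and noise levels must be non-negative")
        if self.noise_model not in _NOISE_MODELS:
            raise ParameterError(f"noise_model must be one of {_NOISE_MODELS}")
        if min(self.n_singles, self.n_trimers, self.n_clusters) < 0:
            raise ParameterError("emitter counts must be non-negative")
        if self.cluster_min_molecules < 1:
            raise ParameterError("cluster_min_molecules must be >= 1")
        if not (self.cluster_packing_um > 0):
            raise ParameterError("cluster_packing_um must be positive")


@dataclass(frozen=True)
class GUVSimParams:
    """Parameters for a set of simulated GUV equatorial images.

    Per-liposome cluster counts are Poisson with rate ``lambda_clusters``;
    cluster footprint areas are lognormal in square micrometres. The membrane
    ring has a Gaussian radial profile of width ``ring_sigma_px``; clusters
    are hard discs centred on the ring so that thresholded-mask area
    measurements agree with the recorded truth area.
    """

    seed: int
    n_liposomes: int = 50
    radius_um_range: tuple[float, float] = (1.5, 2.5)
    lambda_clusters: float = 0.5
    cluster_area_um2_logmu: float = math.log(0.25)
    cluster_area_um2_logsigma: float = 0.3
    membrane_intensity: float = 800.0
    protein_diffuse_intensity: float = 400.0
    cluster_intensity: float = 1200.0
    ring_sigma_px: float = 1.5
    field_size_px: tuple[int, int] = (480, 480)
    pixel_size_um: float = 0.1
    background_level: float = 80.0
    noise_model: str = "poisson_gaussian"
    gaussian_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_liposomes < 0:
            raise ParameterError("n_liposomes must be non-negative")
        lo, hi = self.radius_um_range
        if not (0 < lo <= hi):
            raise ParameterError("radius_um_range must be positive and ordered")
        if self.lambda_clusters < 0:
            raise ParameterError("lambda_clusters must be non-negative")
        if not (self.membrane_intensity > 0):
            raise ParameterError("membrane_intensity must be positive")
        if self.protein_diffuse_intensity < 0 or self.cluster_intensity < 0:
            raise ParameterError("intensities must be non-negative")
        if not (self.ring_sigma_px > 0):
            raise ParameterError("ring_sigma_px must be positive")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ParameterError("background and noise levels must be non-negative")
        if self.noise_model not in _NOISE_MODELS:
            raise ParameterError(f"noise_model must be one of {_NOISE_MODELS}")


@dataclass(frozen=True)
class ColocSimParams:
    """Parameters for a simulated two-channel colocalization pair.

    ``overlap_fraction`` of the B puncta are placed exactly at positions of
    (distinct) A puncta; the rest are kept at least ``6 * psf_sigma_px``
    away from every A punctum so truth overlap is unambiguous.
    """

    seed: int
    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    density_A: float = 0.1          # puncta per um^2
    density_B: float = 0.1
    overlap_fraction: float = 0.5
    punctum_intensity: float = 20000.0
    psf_sigma_px: float = 1.3
    background_level: float = 50.0
    noise_model: str = "poisson_gaussian"
    gaussian_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.density_A < 0 or self.density_B < 0:
            raise ParameterError("densities must be non-negative")
        if not (0 <= self.overlap_fraction <= 1):
            raise ParameterError("overlap_fraction must lie in [0, 1]")
        if not (self.punctum_intensity > 0):
            raise ParameterError("punctum_intensity must be positive")
        if not (self.psf_sigma_px > 0):
            raise ParameterError("psf_sigma_px must be positive")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ParameterError("background and noise levels must be non-negative")
        if self.noise_model not in _NOISE_MODELS:
            raise ParameterError(f"noise_model must be one of {_NOISE_MODELS}")


@dataclass(frozen=True)
class FRAPSimParams:
    """Parameters for a simulated FRAP recovery trace.

    The noise-free trace is 1 during the ``prebleach_frames`` pre-bleach
    frames, drops to ``1 - bleach_depth`` at the bleach, and recovers
    exponentially (time constant ``tau_s``) towards the plateau
    ``(1 - bleach_depth) + bleach_depth * mobile_fraction``.
    """

    seed: int
    n_frames: int = 120
    frame_interval_s: float = 0.5
    prebleach_frames: int = 10
    bleach_depth: float = 0.9
    mobile_fraction: float = 1.0
    tau_s: float = 5.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.prebleach_frames < 3:
            raise ParameterError("prebleach_frames must be >= 3")
        if self.prebleach_frames >= self.n_frames:
            raise ParameterError("prebleach_frames must be < n_frames")
        if not (self.frame_interval_s > 0):
            raise ParameterError("frame_interval_s must be positive")
        if not (0 < self.bleach_depth <= 1):
            raise ParameterError("bleach_depth must lie in (0, 1]")
        if not (0 <= self.mobile_fraction <= 1):
            raise ParameterError("mobile_fraction must lie in [0, 1]")
        if not (self.tau_s > 0):
            raise ParameterError("tau_s must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class EmitterTruth:
    """Ground truth for a simulated DSLB field.

    ``emitters`` holds one row per emitter with columns ``row_px``,
    ``col_px``, ``molecule_count``, ``cluster_id`` (NaN for singles and
    trimers) and ``flux`` (the emitter's integrated intensity in ADU).
    """

    emitters: pd.DataFrame
    total_molecules: int
    molecules_in_clusters: int

    def __post_init__(self) -> None:
        df = self.emitters
        in_clusters = int(df.loc[df["cluster_id"].notna(), "molecule_count"].sum())
        if in_clusters != self.molecules_in_clusters:
            raise ParameterError("molecules_in_clusters inconsistent with emitter table")
        if int(df["molecule_count"].sum()) != self.total_molecules:
            raise ParameterError("total_molecules inconsistent with emitter table")

    @property
    def total_flux(self) -> float:
        """Total emitted intensity, before PSF truncation at the field edge."""
        return float(self.emitters["flux"].sum())


@dataclass
class GUVTruth:
    """Ground truth for a simulated GUV dataset.

    ``liposomes``: one row per liposome (``liposome_id``, ``field_index``,
    ``center_row_px``, ``center_col_px``, ``radius_um``, ``cluster_count``).
    ``clusters``: one row per cluster (``liposome_id``, ``theta_rad``,
    ``area_um2`` nominal disc area, ``area_um2_rendered`` pixel-counted).
    """

    liposomes: pd.DataFrame
    clusters: pd.DataFrame

    @property
    def counts(self) -> np.ndarray:
        return self.liposomes["cluster_count"].to_numpy(dtype=int)


@dataclass
class ColocTruth:
    """Ground truth for a colocalization pair: punctum centroids and the
    realized co-positioned fraction."""

    puncta_A: pd.DataFrame
    puncta_B: pd.DataFrame  # has a boolean column "copositioned"
    overlap_fraction: float


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _pixel_integrated_gaussian(
    shape: tuple[int, int],
    emitters: Sequence[tuple[float, float, float]],
    sigma: float,
    truncate: float = 5.0,
) -> np.ndarray:
    """Render point emitters as pixel-integrated 2-D Gaussians.

    Each emitter ``(row, col, flux)`` deposits ``flux`` times the analytic
    Gaussian mass in each pixel, computed with the error function and
    truncated beyond ``truncate`` sigma from the centre.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=np.float64)
    rad = truncate * sigma
    s = sigma * _SQRT2
    for row, col, flux in emitters:
        r0 = max(0, int(math.floor(row - rad)))
        r1 = min(h, int(math.ceil(row + rad)) + 1)
        c0 = max(0, int(math.floor(col - rad)))
        c1 = min(w, int(math.ceil(col + rad)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=np.float64)
        cc = np.arange(c0, c1, dtype=np.float64)
        fr = 0.5 * (erf((rr + 1.0 - row) / s) - erf((rr - row) / s))
        fc = 0.5 * (erf((cc + 1.0 - col) / s) - erf((cc - col) / s))
        img[r0:r1, c0:c1] += flux * np.outer(fr, fc)
    return img


def _apply_noise(
    clean: np.ndarray, noise_model: str, gaussian_noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply the requested noise model to a non-negative clean image."""
    if noise_model == "none":
        out = clean.copy()
    elif noise_model == "poisson":
        out = rng.poisson(clean).astype(np.float64)
    elif noise_model == "gaussian":
        out = clean + rng.normal(0.0, gaussian_noise_sd, size=clean.shape)
    elif noise_model == "poisson_gaussian":
        out = rng.poisson(clean).astype(np.float64)
        out += rng.normal(0.0, gaussian_noise_sd, size=clean.shape)
    else:  # pragma: no cover - guarded by param validation
        raise ParameterError(f"unknown noise model {noise_model!r}")
    return np.clip(out, 0.0, None)


def _draw_single_intensity(params: FieldSimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-emitter single-fluorophore integrated intensities (ADU)."""
    mean = params.single_intensity_mean
    if params.single_intensity_cv == 0:
        return np.full(n, mean)
    draws = rng.normal(mean, params.single_intensity_cv * mean, size=n)
    # a normal intensity law can graze zero at high CV; keep fluxes physical
    return np.maximum(draws, 0.05 * mean)


def sample_cluster_molecule_counts(
    params: FieldSimParams,
    n: int,
    rng: Optional[np.random.Generator] = None,
    integer: bool = True,
) -> np.ndarray:
    """Draw cluster molecule counts from the truncated lognormal law.

    Draws below ``cluster_min_molecules`` are redrawn (truncation by
    rejection). With ``integer=False`` the continuous pre-rounding values
    are returned; these are what distribution-level diagnostics should test
    against the generating law, since rounding to integers distorts the
    empirical CDF at typical cluster sizes.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.cluster_fixed_molecules is not None:
        vals = np.full(n, float(params.cluster_fixed_molecules))
        return vals.astype(int) if integer else vals
    out = np.empty(n, dtype=np.float64)
    filled = 0
    lo = float(params.cluster_min_molecules)
    while filled < n:
        draws = rng.lognormal(params.cluster_logmu, params.cluster_logsigma, size=n - filled)
        keep = draws[draws >= lo]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    if integer:
        return np.maximum(np.rint(out).astype(int), params.cluster_min_molecules)
    return out


# ---------------------------------------------------------------------------
# DSLB fields
# ---------------------------------------------------------------------------

def simulate_dslb_field(params: FieldSimParams) -> tuple[ImageField, EmitterTruth]:
    """Simulate one DSLB TIRF field and its emitter-level ground truth.

    Singles and trimers are rendered as single emitters whose integrated
    intensity is ``molecule_count`` times a draw from the single-molecule
    intensity law. Each cluster's molecules are rendered as individual
    emitters placed uniformly in a disc of radius
    ``cluster_packing_um * sqrt(n_molecules)`` and share a ``cluster_id``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    sigma = params.psf_sigma_px
    margin = 1.0

    rows: list[dict] = []
    render: list[tuple[float, float, float]] = []

    def _place_uniform(n: int) -> np.ndarray:
        pos = np.empty((n, 2))
        pos[:, 0] = rng.uniform(margin, h - margin, size=n)
        pos[:, 1] = rng.uniform(margin, w - margin, size=n)
        return pos

    # singles
    pos = _place_uniform(params.n_singles)
    flux1 = _draw_single_intensity(params, rng, params.n_singles)
    for (r, c), f in zip(pos, flux1):
        rows.append(dict(row_px=r, col_px=c, molecule_count=1, cluster_id=np.nan, flux=f))
        render.append((r, c, f))

    # trimers: one emitter carrying exactly three molecules
    pos = _place_uniform(params.n_trimers)
    flux3 = 3.0 * _draw_single_intensity(params, rng, params.n_trimers)
    for (r, c), f in zip(pos, flux3):
        rows.append(dict(row_px=r, col_px=c, molecule_count=3, cluster_id=np.nan, flux=f))
        render.append((r, c, f))

    # clusters: molecule-by-molecule placement inside a disc
    counts = sample_cluster_molecule_counts(params, params.n_clusters, rng=rng, integer=True)
    for cid, n_mol in enumerate(counts):
        disc_r_px = params.cluster_packing_um * math.sqrt(n_mol) / params.pixel_size_um
        keep_out = disc_r_px + margin
        if 2 * keep_out >= min(h, w):
            raise SizingError("cluster disc does not fit in the field")
        cy = rng.uniform(keep_out, h - keep_out)
        cx = rng.uniform(keep_out, w - keep_out)
        rad = disc_r_px * np.sqrt(rng.uniform(size=n_mol))
        ang = rng.uniform(0.0, 2.0 * math.pi, size=n_mol)
        flux_m = _draw_single_intensity(params, rng, int(n_mol))
        for rr, aa, f in zip(rad, ang, flux_m):
            r = cy + rr * math.sin(aa)
            c = cx + rr * math.cos(aa)
            rows.append(dict(row_px=r, col_px=c, molecule_count=1, cluster_id=cid, flux=f))
            render.append((r, c, f))

    clean = _pixel_integrated_gaussian((h, w), render, sigma)
    clean += params.background_level
    pixels = _apply_noise(clean, params.noise_model, params.gaussian_noise_sd, rng)

    emitters = pd.DataFrame(
        rows, columns=["row_px", "col_px", "molecule_count", "cluster_id", "flux"]
    )
    if emitters.empty:
        emitters = emitters.astype(
            {"row_px": float, "col_px": float, "molecule_count": int, "cluster_id": float, "flux": float}
        )
    truth = EmitterTruth(
        emitters=emitters,
        total_molecules=int(emitters["molecule_count"].sum()),
        molecules_in_clusters=int(
            emitters.loc[emitters["cluster_id"].notna(), "molecule_count"].sum()
        ),
    )
    image = ImageField(pixels=pixels, pixel_size_um=params.pixel_size_um, channel_name="dslb")
    return image, truth


# ---------------------------------------------------------------------------
# GUV datasets
# ---------------------------------------------------------------------------

def _place_cluster_angles(
    rng: np.random.Generator, n: int, min_sep_rad: np.ndarray
) -> np.ndarray:
    """Draw ``n`` angles on the ring with pairwise separation constraints.

    ``min_sep_rad[i]`` is the half-footprint of cluster ``i`` in radians;
    two clusters must be separated by the sum of their half-footprints plus
    a small guard so their discs stay disjoint.
    """
    angles: list[float] = []
    for i in range(n):
        for _ in range(200):
            cand = rng.uniform(0.0, 2.0 * math.pi)
            ok = True
            for j, a in enumerate(angles):
                d = abs(cand - a)
                d = min(d, 2.0 * math.pi - d)
                if d < min_sep_rad[i] + min_sep_rad[j]:
                    ok = False
                    break
            if ok:
                break
        angles.append(cand)
    return np.asarray(angles)


def simulate_guv_set(
    params: GUVSimParams,
) -> tuple[list[tuple[ImageField, ImageField]], GUVTruth]:
    """Simulate a GUV dataset: (membrane, protein) image pairs plus truth.

    Liposomes are laid out on a jittered grid so rings never overlap or
    touch the field border; as many fields as needed are generated to host
    ``n_liposomes``. Raises :class:`SizingError` if even one liposome cannot
    fit in the requested field size.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    px = params.pixel_size_um
    max_r_px = params.radius_um_range[1] / px
    # grid cell leaves room for the ring, its Gaussian profile, and jitter
    cell = int(math.ceil(2.0 * (max_r_px + 4.0 * params.ring_sigma_px + 4.0)))
    n_rows = (h - 4) // cell
    n_cols = (w - 4) // cell
    capacity = n_rows * n_cols
    if params.n_liposomes > 0 and capacity < 1:
        raise SizingError(
            f"field {params.field_size_px} cannot host a liposome of radius "
            f"{params.radius_um_range[1]} um"
        )

    n_fields = 0 if params.n_liposomes == 0 else math.ceil(params.n_liposomes / capacity)
    lip_rows: list[dict] = []
    clu_rows: list[dict] = []
    pairs: list[tuple[ImageField, ImageField]] = []
    lip_id = 0

    for f_idx in range(max(n_fields, 1)):
        membrane = np.zeros((h, w))
        protein = np.zeros((h, w))
        n_here = min(capacity, params.n_liposomes - lip_id) if params.n_liposomes else 0
        slots = [(i, j) for i in range(n_rows) for j in range(n_cols)][:n_here]
        for i, j in slots:
            cy = 2 + i * cell + cell / 2.0 + rng.uniform(-2.0, 2.0)
            cx = 2 + j * cell + cell / 2.0 + rng.uniform(-2.0, 2.0)
            radius_um = rng.uniform(*params.radius_um_range)
            r_px = radius_um / px

            reach = int(math.ceil(r_px + 4.0 * params.ring_sigma_px + 1))
            r0, r1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
            c0, c1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
            ring = np.exp(-((d - r_px) ** 2) / (2.0 * params.ring_sigma_px**2))
            membrane[r0:r1, c0:c1] += params.membrane_intensity * ring
            protein[r0:r1, c0:c1] += params.protein_diffuse_intensity * ring

            n_clusters = rng.poisson(params.lambda_clusters)
            if n_clusters > 0:
                areas = rng.lognormal(
                    params.cluster_area_um2_logmu, params.cluster_area_um2_logsigma, size=n_clusters
                )
                disc_r_px = np.sqrt(areas / math.pi) / px
                half_foot = (disc_r_px + 1.5) / r_px
                thetas = _place_cluster_angles(rng, n_clusters, half_foot)
                for theta, a_um2, dr in zip(thetas, areas, disc_r_px):
                    ky = cy + r_px * math.sin(theta)
                    kx = cx + r_px * math.cos(theta)
                    dd = np.hypot(yy + 0.5 - ky, xx + 0.5 - kx)
                    disc = dd < dr
                    protein[r0:r1, c0:c1][disc] += params.cluster_intensity
                    clu_rows.append(
                        dict(
                            liposome_id=lip_id,
                            theta_rad=theta,
                            area_um2=a_um2,
                            area_um2_rendered=float(disc.sum()) * px**2,
                        )
                    )
            lip_rows.append(
                dict(
                    liposome_id=lip_id,
                    field_index=f_idx,
                    center_row_px=cy,
                    center_col_px=cx,
                    radius_um=radius_um,
                    cluster_count=int(n_clusters),
                )
            )
            lip_id += 1

        membrane += params.background_level
        protein += params.background_level
        mem_px = _apply_noise(membrane, params.noise_model, params.gaussian_noise_sd, rng)
        pro_px = _apply_noise(protein, params.noise_model, params.gaussian_noise_sd, rng)
        pairs.append(
            (
                ImageField(mem_px, px, channel_name="membrane"),
                ImageField(pro_px, px, channel_name="protein"),
            )
        )

    liposomes = pd.DataFrame(
        lip_rows,
        columns=[
            "liposome_id",
            "field_index",
            "center_row_px",
            "center_col_px",
            "radius_um",
            "cluster_count",
        ],
    )
    clusters = pd.DataFrame(
        clu_rows, columns=["liposome_id", "theta_rad", "area_um2", "area_um2_rendered"]
    )
    return pairs, GUVTruth(liposomes=liposomes, clusters=clusters)


# ---------------------------------------------------------------------------
# colocalization pairs
# ---------------------------------------------------------------------------

def simulate_coloc_pair(params: ColocSimParams) -> tuple[ImageField, ImageField, ColocTruth]:
    """Simulate a two-channel field with a controlled co-positioned fraction.

    ``round(overlap_fraction * n_B)`` B puncta sit exactly on (distinct) A
    puncta; the rest are kept at least six PSF sigma from every A centroid
    (so that threshold-mask footprints of distinct puncta stay disjoint)
    and from each other. Raises :class:`ParameterError` when the requested
    densities cannot be placed in the field.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_size_px
    px = params.pixel_size_um
    area_um2 = h * w * px * px
    n_a = int(round(params.density_A * area_um2))
    n_b = int(round(params.density_B * area_um2))
    n_co = int(round(params.overlap_fraction * n_b))
    if n_co > n_a:
        raise ParameterError(
            "overlap_fraction requires more co-positioned B puncta than A puncta exist"
        )
    sep = 6.0 * params.psf_sigma_px
    margin = 3.0 * params.psf_sigma_px + 1.0
    if (n_a + n_b) * math.pi * sep**2 > 0.5 * h * w:
        raise ParameterError("requested densities exceed the field's placement capacity")

    def _place(n: int, existing: list[tuple[float, float]], min_d: float) -> list[tuple[float, float]]:
        placed: list[tuple[float, float]] = []
        for _ in range(n):
            for attempt in range(500):
                cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
                if all(
                    math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_d
                    for p in existing + placed
                ):
                    placed.append(cand)
                    break
            else:
                raise ParameterError("could not place puncta at the requested density")
        return placed

    pos_a = _place(n_a, [], sep)
    co_idx = rng.choice(n_a, size=n_co, replace=False) if n_co else np.array([], dtype=int)
    pos_b = [pos_a[i] for i in co_idx]
    pos_b += _place(n_b - n_co, pos_a, 6.0 * params.psf_sigma_px)

    flux = params.punctum_intensity
    img_a = _pixel_integrated_gaussian((h, w), [(r, c, flux) for r, c in pos_a], params.psf_sigma_px)
    img_b = _pixel_integrated_gaussian((h, w), [(r, c, flux) for r, c in pos_b], params.psf_sigma_px)
    img_a += params.background_level
    img_b += params.background_level
    pix_a = _apply_noise(img_a, params.noise_model, params.gaussian_noise_sd, rng)
    pix_b = _apply_noise(img_b, params.noise_model, params.gaussian_noise_sd, rng)

    df_a = pd.DataFrame(pos_a, columns=["row_px", "col_px"])
    df_b = pd.DataFrame(pos_b, columns=["row_px", "col_px"])
    df_b["copositioned"] = [i < n_co for i in range(n_b)]
    truth = ColocTruth(
        puncta_A=df_a,
        puncta_B=df_b,
        overlap_fraction=(n_co / n_b) if n_b else 0.0,
    )
    return (
        ImageField(pix_a, px, channel_name="A"),
        ImageField(pix_b, px, channel_name="B"),
        truth,
    )


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def frap_noise_free_value(params: FRAPSimParams, t_post_s: float) -> float:
    """Closed-form noise-free trace value at time ``t_post_s`` after bleach."""
    floor = 1.0 - params.bleach_depth
    plateau_gain = params.bleach_depth * params.mobile_fraction
    return floor + plateau_gain * (1.0 - math.exp(-t_post_s / params.tau_s))


def simulate_frap_trace(params: FRAPSimParams) -> tuple[FRAPTrace, dict]:
    """Simulate a FRAP recovery trace; returns the trace and its truth.

    The truth dictionary holds ``mobile_fraction`` and ``tau_s``.
    """
    rng = np.random.default_rng(params.seed)
    times = np.arange(params.n_frames) * params.frame_interval_s
    values = np.ones(params.n_frames)
    b = params.prebleach_frames
    t_post = times[b:] - times[b]
    values[b:] = [frap_noise_free_value(params, t) for t in t_post]
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=params.n_frames)
    trace = FRAPTrace(times_s=times, bleach_roi=values, bleach_frame_index=b)
    return trace, {"mobile_fraction": params.mobile_fraction, "tau_s": params.tau_s}
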