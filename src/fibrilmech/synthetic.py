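"""Synthetic AFM data with known ground truth.

Three generators emulate the data the fibril analysis consumes, so every
downstream stage can be validated by parameter recovery:

* **Force curves** — a Sneddon cone forward model
  ``F = (2/π)·tanθ · E/(1−ν²) · δ²`` with consistent piezo/deflection
  channels for the stated spring constant, additive white Gaussian force
  noise and optional linear baseline drift.  The geometric prefactor is the
  same constant the analyzer's ideal area function assumes, which gives an
  exact analytic round trip.
* **Topography images** — one D-banded cylindrical fibril (semi-elliptic
  cross-section, sinusoidal axial height modulation) on a rough flat
  substrate, in a dry or a hydrated (swollen) state, with optional grayscale
  tip dilation by a spherical-cap structuring element.
* **Cohorts** — per-fibril modulus tables drawn per group from a lognormal
  (default) or zero-truncated normal distribution parameterized by the
  arithmetic group mean and SD.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .force_spectroscopy import (
    CONE_GEOMETRY_CONSTANT,
    CantileverCalibration,
    ForceCurve,
)
from .topography import TopographyImage

__all__ = [
    "CurveSimSpec",
    "FibrilImageSpec",
    "GroupSpec",
    "CohortSimSpec",
    "generate_force_curve",
    "generate_fibril_image",
    "generate_cohort",
    "sneddon_prefactor_nn_per_nm2",
    "max_force_nn",
    "write_cohort_csv",
    "read_cohort_csv",
]


def _require_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveSimSpec:
    """Ground-truth parameters of one simulated indentation curve.

    ``contact_point_nm`` is the piezo position at which the tip first touches
    the fibril; the approach ramps from ``contact_point − precontact_range``
    (default twice the maximum indentation) up to the piezo position that
    produces ``max_indentation_nm`` of true indentation.
    """

    modulus_true_pa: float
    poisson_sample: float = 0.5
    tip_half_angle_deg: float = 35.0
    spring_constant_n_per_m: float = 0.24
    contact_point_nm: float = 200.0
    max_indentation_nm: float = 50.0
    noise_sd_nn: float = 0.0
    drift_slope_nn_per_nm: float = 0.0
    points_per_segment: int = 512
    precontact_range_nm: float | None = None
    medium: str = "PBS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("modulus_true_pa", "poisson_sample", "tip_half_angle_deg",
                     "spring_constant_n_per_m", "contact_point_nm",
                     "max_indentation_nm", "noise_sd_nn", "drift_slope_nn_per_nm"):
            _require_finite(name, getattr(self, name))
        if self.modulus_true_pa <= 0:
            raise ValueError("true modulus must be positive")
        if not 0 <= self.poisson_sample <= 0.5:
            raise ValueError("sample Poisson ratio must lie in [0, 0.5]")
        if not 0 < self.tip_half_angle_deg < 90:
            raise ValueError("tip half-angle must lie in (0°, 90°)")
        if self.spring_constant_n_per_m <= 0:
            raise ValueError("spring constant must be positive")
        if self.max_indentation_nm < 0:
            raise ValueError("maximum indentation must be non-negative")
        if self.noise_sd_nn < 0:
            raise ValueError("noise SD must be non-negative")
        if self.points_per_segment < 16:
            raise ValueError("need at least 16 points per segment")
        if self.precontact_range_nm is not None and self.precontact_range_nm <= 0:
            raise ValueError("pre-contact range must be positive")

    @property
    def precontact_nm(self) -> float:
        if self.precontact_range_nm is not None:
            return self.precontact_range_nm
        return max(2.0 * self.max_indentation_nm, 100.0)


def sneddon_prefactor_nn_per_nm2(spec: CurveSimSpec) -> float:
    """Load-curve prefactor C with F[nN] = C·δ[nm]²."""
    k_pa = (
        CONE_GEOMETRY_CONSTANT
        * np.tan(np.radians(spec.tip_half_angle_deg))
        * spec.modulus_true_pa
        / (1.0 - spec.poisson_sample**2)
    )
    return float(k_pa * 1e-9)  # Pa·nm²·1e-18 m²/nm² → N → 1e9 nN


def max_force_nn(spec: CurveSimSpec) -> float:
    """Peak load of the noiseless forward model, in nN."""
    return sneddon_prefactor_nn_per_nm2(spec) * spec.max_indentation_nm**2


def generate_force_curve(spec: CurveSimSpec) -> ForceCurve:
    """Simulate an approach/retract force–displacement record.

    The piezo is ramped uniformly; in contact the true indentation at piezo
    position z solves ``z − z₀ = δ + F(δ)/k`` (tip travel = indentation +
    cantilever bending), which for the quadratic cone load law has the closed
    form ``δ = (−1 + √(1 + 4a(z − z₀)))/(2a)`` with ``a = C/k``.
    """
    rng = np.random.default_rng(spec.seed)
    c_nn = sneddon_prefactor_nn_per_nm2(spec)
    k = spec.spring_constant_n_per_m
    z0 = spec.contact_point_nm
    d_max = max_force_nn(spec) / k
    z_start = z0 - spec.precontact_nm
    z_end = z0 + spec.max_indentation_nm + d_max
    n = spec.points_per_segment
    z = np.linspace(z_start, z_end, n)

    a = c_nn / k  # 1/nm
    dz = np.clip(z - z0, 0.0, None)
    if a > 0:
        delta = (-1.0 + np.sqrt(1.0 + 4.0 * a * dz)) / (2.0 * a)
    else:  # pragma: no cover - a > 0 whenever modulus > 0
        delta = dz
    force_nn = c_nn * delta**2
    d_clean = force_nn / k

    def channel(zz: np.ndarray, clean: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, spec.noise_sd_nn, len(zz)) if spec.noise_sd_nn > 0 else 0.0
        drift = spec.drift_slope_nn_per_nm * (zz - z_start)
        return clean + (noise + drift) / k

    d_approach = channel(z, d_clean)
    d_retract = channel(z[::-1], d_clean[::-1])

    z_all = np.concatenate([z, z[::-1]])
    d_all = np.concatenate([d_approach, d_retract])
    seg = np.array(["approach"] * n + ["retract"] * n)
    calib = CantileverCalibration(spring_constant_n_per_m=k)
    meta = {
        "modulus_true_pa": spec.modulus_true_pa,
        "contact_point_true_nm": z0,
        "max_indentation_true_nm": spec.max_indentation_nm,
        "tip_half_angle_deg": spec.tip_half_angle_deg,
        "seed": spec.seed,
    }
    return ForceCurve(z_nm=z_all, deflection_nm=d_all, segment=seg,
                      medium=spec.medium, calibration=calib, metadata=meta)


# ---------------------------------------------------------------------------
# topography images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FibrilImageSpec:
    """Ground truth for one D-banded fibril topography.

    The wet state scales both the height and the apparent width by
    ``swelling_true`` (isotropic cross-section dilation); the axial D-period is
    unchanged, reflecting the constant-length assumption of height-based
    swelling estimation.
    """

    height_dry_nm: float = 26.0
    swelling_true: float = 2.6
    d_period_nm: float = 67.0
    band_amplitude_frac: float = 0.1
    fibril_width_nm: float = 80.0
    pixel_size_nm: float = 2.0
    image_shape: tuple[int, int] = (128, 512)
    substrate_roughness_sd_nm: float = 0.2
    tip_radius_nm: float = 0.0
    axis_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_dry_nm <= 0 or self.fibril_width_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("heights, widths and pixel size must be positive")
        if self.swelling_true < 1:
            raise ValueError("swelling fold must be ≥ 1")
        if self.d_period_nm <= 2 * self.pixel_size_nm:
            raise ValueError("D-period must exceed twice the pixel size (Nyquist)")
        if not 0 <= self.band_amplitude_frac <= 0.5:
            raise ValueError("band amplitude fraction must lie in [0, 0.5]")
        if self.substrate_roughness_sd_nm < 0 or self.tip_radius_nm < 0:
            raise ValueError("roughness and tip radius must be non-negative")
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image too small")

    def width_nm(self, state: str) -> float:
        return self.fibril_width_nm * (self.swelling_true if state == "wet" else 1.0)

    def height_nm(self, state: str) -> float:
        return self.height_dry_nm * (self.swelling_true if state == "wet" else 1.0)


def _spherical_cap_structure(radius_nm: float, pixel_size_nm: float):
    r_px = radius_nm / pixel_size_nm
    half = int(np.ceil(r_px))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    d2 = (yy.astype(float) ** 2 + xx.astype(float) ** 2) * pixel_size_nm**2
    footprint = d2 <= radius_nm**2
    cap = np.zeros_like(d2)
    cap[footprint] = np.sqrt(radius_nm**2 - d2[footprint]) - radius_nm
    return footprint, cap


def generate_fibril_image(spec: FibrilImageSpec, state: str = "dry") -> TopographyImage:
    """Render one fibril above a near-flat substrate as a calibrated height map."""
    if state not in ("dry", "wet"):
        raise ValueError("state must be 'dry' or 'wet'")
    rows, cols = spec.image_shape
    px = spec.pixel_size_nm
    height = spec.height_nm(state)
    width = spec.width_nm(state)
    if width >= 0.9 * min(rows, cols) * px:
        raise ValueError(
            f"image too small: fibril width {width:.1f} nm does not fit in "
            f"{rows}×{cols} px at {px} nm/px"
        )
    rng = np.random.default_rng(spec.seed)
    y = (np.arange(rows, dtype=float) - (rows - 1) / 2.0) * px
    x = (np.arange(cols, dtype=float) - (cols - 1) / 2.0) * px
    xx, yy = np.meshgrid(x, y)
    phi = np.radians(spec.axis_angle_deg)
    s = xx * np.cos(phi) + yy * np.sin(phi)       # axial coordinate
    t = -xx * np.sin(phi) + yy * np.cos(phi)      # perpendicular offset
    hw = width / 2.0
    envelope = np.sqrt(np.clip(1.0 - (t / hw) ** 2, 0.0, None))
    modulation = 1.0 + spec.band_amplitude_frac * np.sin(2.0 * np.pi * s / spec.d_period_nm)
    fibril = height * envelope * modulation
    substrate = (
        rng.normal(0.0, spec.substrate_roughness_sd_nm, (rows, cols))
        if spec.substrate_roughness_sd_nm > 0
        else np.zeros((rows, cols))
    )
    heights = fibril + substrate
    if spec.tip_radius_nm > 0:
        footprint, cap = _spherical_cap_structure(spec.tip_radius_nm, px)
        heights = ndimage.grey_dilation(heights, footprint=footprint, structure=cap)
    meta = {
        "height_true_nm": height,
        "swelling_true": spec.swelling_true,
        "d_period_true_nm": spec.d_period_nm,
        "axis_angle_deg": spec.axis_angle_deg,
        "fibril_width_nm": width,
        "seed": spec.seed,
    }
    return TopographyImage(heights_nm=heights, pixel_size_nm=px,
                           medium="PBS" if state == "wet" else "air",
                           state=state, metadata=meta)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One genotype×medium cohort group parameterized on the arithmetic scale."""

    genotype: str
    medium: str
    mean_pa: float
    sd_pa: float
    n: int

    def __post_init__(self) -> None:
        if self.mean_pa <= 0:
            raise ValueError("group mean must be positive")
        if self.sd_pa < 0:
            raise ValueError("group SD must be non-negative")
        if self.n < 2:
            raise ValueError("each group needs n ≥ 2")

    @property
    def label(self) -> str:
        return f"{self.genotype}-{self.medium}"


@dataclass(frozen=True)
class CohortSimSpec:
    groups: tuple[GroupSpec, ...]
    distribution: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.distribution not in ("lognormal", "normal-truncated-at-0"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # match the arithmetic mean and SD of the lognormal
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw per-fibril moduli for every group; reproducible under the seed.

    Returns the cohort table with columns ``fibril_id, genotype, medium, sex,
    modulus_Pa``.  Lognormal draws are parameterized so their *arithmetic*
    mean and SD equal the requested values.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.groups:
        if group.sd_pa == 0:
            values = np.full(group.n, group.mean_pa)
        elif spec.distribution == "lognormal":
            mu, sigma = _lognormal_params(group.mean_pa, group.sd_pa)
            values = rng.lognormal(mu, sigma, group.n)
        else:
            a = (0.0 - group.mean_pa) / group.sd_pa
            dist = stats.truncnorm(a, np.inf, loc=group.mean_pa, scale=group.sd_pa)
            values = dist.rvs(group.n, random_state=rng)
        sexes = rng.choice(["M", "F"], size=group.n)
        for i, (val, sex) in enumerate(zip(values, sexes)):
            rows.append(
                {
                    "fibril_id": f"{group.label}-{i:03d}",
                    "genotype": group.genotype,
                    "medium": group.medium,
                    "sex": sex,
                    "modulus_Pa": float(val),
                }
            )
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"fibril_id", "genotype", "medium", "modulus_Pa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    if "sex" not in df.columns:
        df["sex"] = "NA"
    return df
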