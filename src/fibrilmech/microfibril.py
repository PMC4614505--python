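"""Microfibril unit-cell, mass, density and tangent-modulus arithmetic.

The collagen microfibril packs into a triclinic unit cell (the 3HR2 in-situ
structure: a ≈ 40 Å, b ≈ 27 Å, c ≈ 678 Å, α ≈ 89.2°, β ≈ 94.6°, γ ≈ 105.6°).
This module provides the derived arithmetic applied to such cells and to
atomistic compression results: cell volume, trimer masses from chain
composition (heterotrimer 2×α1 + 1×α2 vs homotrimer 3×α1), density ratios,
percent differences, and the tangent (transverse elastic) modulus read off a
polynomial stress–strain fit at a prescribed stress level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TriclinicCell",
    "ChainComposition",
    "StressStrainSeries",
    "DensityComparison",
    "cell_volume",
    "lattice_vectors",
    "trimer_mass",
    "density_ratio",
    "percent_difference",
    "fit_stress_strain",
    "tangent_modulus",
]


@dataclass(frozen=True)
class TriclinicCell:
    """Triclinic unit cell: edges in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"angle {name}={ang} must lie in (0°, 180°)")
        if self._volume_discriminant() <= 1e-6:  # also rejects near-degenerate cells
            raise ValueError("angles do not define a positive-definite cell metric")

    def _volume_discriminant(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return float(1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TriclinicCell":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
                   alpha=float(d["alpha"]), beta=float(d["beta"]), gamma=float(d["gamma"]))


def cell_volume(cell: TriclinicCell) -> float:
    """Cell volume in ų via the standard crystallographic formula.

    V = abc·√(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ).
    """
    return cell.a * cell.b * cell.c * float(np.sqrt(cell._volume_discriminant()))


def lattice_vectors(cell: TriclinicCell) -> np.ndarray:
    """Explicit Cartesian lattice vectors (rows), for triple-product checks.

    a along x; b in the xy-plane at angle γ from a; c fixed by α, β.
    """
    ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = np.sin(np.radians(cell.gamma))
    va = np.array([cell.a, 0.0, 0.0])
    vb = np.array([cell.b * cg, cell.b * sg, 0.0])
    cx = cell.c * cb
    cy = cell.c * (ca - cb * cg) / sg
    cz2 = cell.c**2 - cx**2 - cy**2
    if cz2 <= 0:
        raise ValueError("angles do not define a positive-definite cell metric")
    vc = np.array([cx, cy, np.sqrt(cz2)])
    return np.vstack([va, vb, vc])


@dataclass(frozen=True)
class ChainComposition:
    """Trimer composition: chain masses (kDa) and per-trimer stoichiometry."""

    chain_masses_kda: Mapping[str, float]
    stoichiometry: Mapping[str, int]

    def __post_init__(self) -> None:
        for chain, mass in self.chain_masses_kda.items():
            if mass <= 0:
                raise ValueError(f"chain {chain!r} mass must be positive")
        total = sum(self.stoichiometry.values())
        if total != 3:
            raise ValueError(f"trimer stoichiometry must sum to 3 chains, got {total}")
        missing = set(self.stoichiometry) - set(self.chain_masses_kda)
        if missing:
            raise ValueError(f"no mass given for chains: {sorted(missing)}")


def trimer_mass(comp: ChainComposition) -> float:
    """Total trimer mass in kDa: Σ count·chain mass."""
    return float(
        sum(n * comp.chain_masses_kda[chain] for chain, n in comp.stoichiometry.items())
    )


@dataclass(frozen=True)
class DensityComparison:
    ratio: float                 # (mass_x/vol_x) / (mass_ref/vol_ref)
    percent_difference: float    # (1 − ratio)·100; positive = x less dense


def density_ratio(mass_x_kda: float, vol_x_a3: float,
                  mass_ref_kda: float, vol_ref_a3: float) -> DensityComparison:
    """Density of x relative to a reference, and the percent deficit."""
    if min(mass_x_kda, vol_x_a3, mass_ref_kda, vol_ref_a3) <= 0:
        raise ValueError("masses and volumes must be positive")
    ratio = (mass_x_kda / vol_x_a3) / (mass_ref_kda / vol_ref_a3)
    return DensityComparison(ratio=float(ratio),
                             percent_difference=float((1.0 - ratio) * 100.0))


def percent_difference(x: float, ref: float) -> float:
    """Signed percent difference (ref − x)/ref·100 with ref as the baseline."""
    if ref == 0:
        raise ValueError("reference must be non-zero")
    return float((ref - x) / ref * 100.0)


# ---------------------------------------------------------------------------
# stress–strain
# ---------------------------------------------------------------------------


@dataclass
class StressStrainSeries:
    """Applied stress levels (Pa) vs strain responses, with a polynomial fit.

    ``coefficients`` are ascending-power coefficients of σ(ε); filled by
    :func:`fit_stress_strain`.
    """

    stress_pa: np.ndarray
    strain: np.ndarray
    degree: int = 2
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stress_pa = np.asarray(self.stress_pa, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if len(self.stress_pa) != len(self.strain):
            raise ValueError("stress and strain series must have equal length")
        if len(np.unique(self.stress_pa)) != len(self.stress_pa):
            raise ValueError("stress levels must be distinct")
        if len(self.stress_pa) < self.degree + 1:
            raise ValueError("need at least degree+1 points")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StressStrainSeries":
        return cls(stress_pa=np.asarray(d["stress_pa"], dtype=float),
                   strain=np.asarray(d["strain"], dtype=float),
                   degree=int(d.get("degree", 2)))


def fit_stress_strain(series: StressStrainSeries, degree: int | None = None,
                      through_origin: bool = True) -> np.ndarray:
    """Least-squares polynomial σ(ε); returns ascending coefficients.

    ``through_origin=True`` omits the constant term (zero stress at zero
    strain).  The fitted coefficients are also stored on the series.
    """
    degree = series.degree if degree is None else degree
    if degree < 1:
        raise ValueError("degree must be ≥ 1")
    if len(series.strain) < degree + (0 if through_origin else 1):
        raise ValueError("not enough points for the requested degree")
    eps, sig = series.strain, series.stress_pa
    powers = np.arange(1 if through_origin else 0, degree + 1)
    basis = eps[:, None] ** powers[None, :]
    sol, *_ = np.linalg.lstsq(basis, sig, rcond=None)
    coeffs = np.zeros(degree + 1)
    coeffs[powers] = sol
    series.degree = degree
    series.coefficients = coeffs
    return coeffs


def tangent_modulus(coefficients: Sequence[float], stress_level_pa: float,
                    strain_max: float, strain_min: float = 0.0) -> float:
    """Slope dσ/dε of the fitted stress–strain polynomial at a stress level.

    Solves σ(ε*) = stress_level by bisection on [strain_min, strain_max]
    (σ must be strictly increasing there) and evaluates the derivative at ε*.
    """
    poly = np.polynomial.Polynomial(np.asarray(coefficients, dtype=float))
    dpoly = poly.deriv()
    grid = np.linspace(strain_min, strain_max, 256)
    if np.any(dpoly(grid[1:]) <= 0):
        raise ValueError("stress–strain fit is not strictly increasing over the range")
    lo, hi = poly(strain_min), poly(strain_max)
    if not lo <= stress_level_pa <= hi:
        raise ValueError(
            f"stress level {stress_level_pa:.6g} Pa outside the fitted range "
            f"[{lo:.6g}, {hi:.6g}] Pa"
        )
    root = optimize.bisect(lambda e: poly(e) - stress_level_pa, strain_min, strain_max,
                           xtol=1e-15)
    return float(dpoly(root))
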