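"""Contact-mechanics analysis of AFM force–displacement curves.

Converts raw piezo/deflection records from cantilever-based nanoindentation of
single collagen fibrils into an *indentation modulus* through the standard
Oliver–Pharr/Sneddon chain:

1. cantilever calibration (thermal/equipartition method),
2. contact-point detection and baseline correction,
3. conversion to force and tip–sample separation (indentation),
4. contact stiffness ``S_c = dF/dδ`` at maximum load,
5. contact depth ``h_c = h_max − ε·P_max/S_c``,
6. projected contact area ``A_c(h_c)`` (ideal tip geometry or calibrated
   polynomial),
7. reduced modulus ``E_r = √π/(2β) · S_c/√A_c``,
8. sample modulus ``E_sample = (1 − ν²)·E_r`` (or the exact two-body relation).

Because indentation of a transversely isotropic fibril mixes transverse
compression and longitudinal tension, the extracted quantity is reported as an
indentation modulus rather than a pure transverse Young's modulus.

Working units follow AFM practice: lengths in nm, forces in nN, stiffness in
N/m (note nN/nm ≡ N/m), moduli in Pa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

__all__ = [
    "BOLTZMANN_J_PER_K",
    "EPSILON_CONE",
    "EPSILON_PARABOLOID",
    "CONE_GEOMETRY_CONSTANT",
    "CantileverCalibration",
    "ForceCurve",
    "TipAreaFunction",
    "ContactPointResult",
    "StiffnessFit",
    "AnalysisConfig",
    "ContactAnalysis",
    "thermal_spring_constant",
    "find_contact_point",
    "to_force_and_separation",
    "contact_stiffness",
    "contact_depth",
    "area_at_depth",
    "reduced_modulus",
    "sample_modulus",
    "analyze_curve",
    "analyze_batch",
    "read_curve_tsv",
    "write_curve_tsv",
]

BOLTZMANN_J_PER_K = 1.380649e-23

#: Oliver–Pharr intercept factor for a conical indenter, 2(π−2)/π ≈ 0.7268.
EPSILON_CONE = 2.0 * (np.pi - 2.0) / np.pi
#: Textbook paraboloid-of-revolution value.
EPSILON_PARABOLOID = 0.75

#: Geometric prefactor of the Sneddon cone load relation
#: F = c·tanθ · E/(1−ν²) · δ².  Shared with the synthetic forward model.
CONE_GEOMETRY_CONSTANT = 2.0 / np.pi


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CantileverCalibration:
    """Cantilever calibration record.

    Parameters
    ----------
    spring_constant_n_per_m
        Flexural spring constant ``k`` in N/m.
    invols_nm_per_v
        Inverse optical lever sensitivity; ``None`` if the deflection channel
        is already in nm.
    temperature_k
        Bath temperature during thermal calibration.
    thermal_correction
        Mode-shape correction applied in the equipartition formula; 0.971 for
        the first flexural mode of a rectangular lever.
    """

    spring_constant_n_per_m: float
    invols_nm_per_v: float | None = None
    temperature_k: float = 294.0
    thermal_correction: float = 0.971

    def __post_init__(self) -> None:
        if not np.isfinite(self.spring_constant_n_per_m) or self.spring_constant_n_per_m <= 0:
            raise ValueError("spring constant must be positive and finite")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")


def thermal_spring_constant(
    deflection_nm: Sequence[float],
    temperature_k: float = 294.0,
    correction: float = 0.971,
) -> float:
    """Spring constant from thermal deflection noise (equipartition).

    ``k = correction · k_B·T / var(d)`` with the deflection series in nm and a
    detrended, purely thermal baseline.  Returns k in N/m.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    d = np.asarray(deflection_nm, dtype=float)
    var_nm2 = float(np.var(d))
    if var_nm2 <= 0:
        raise ValueError("deflection series has zero variance; cannot calibrate")
    var_m2 = var_nm2 * 1e-18
    return correction * BOLTZMANN_J_PER_K * temperature_k / var_m2


# ---------------------------------------------------------------------------
# force curve container and I/O
# ---------------------------------------------------------------------------


@dataclass
class ForceCurve:
    """A raw force–displacement record.

    ``z_nm`` is piezo displacement (increasing toward the sample), ``deflection_nm``
    the cantilever deflection, ``segment`` a per-point label (``"approach"`` or
    ``"retract"``).  ``z`` must be strictly monotone within each segment.
    """

    z_nm: np.ndarray
    deflection_nm: np.ndarray
    segment: np.ndarray
    medium: str = "PBS"
    calibration: CantileverCalibration | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (len(self.z_nm) == len(self.deflection_nm) == len(self.segment)):
            raise ValueError("z, deflection and segment series must have equal length")
        for name in ("approach", "retract"):
            z = self.z_nm[self.segment == name]
            if len(z) > 1:
                dz = np.diff(z)
                if not (np.all(dz > 0) or np.all(dz < 0)):
                    raise ValueError(f"z must be strictly monotone within the {name} segment")

    def segment_arrays(self, name: str = "approach") -> tuple[np.ndarray, np.ndarray]:
        mask = self.segment == name
        return self.z_nm[mask], self.deflection_nm[mask]

    @property
    def spring_constant(self) -> float:
        if self.calibration is None:
            raise ValueError("curve has no attached cantilever calibration")
        return self.calibration.spring_constant_n_per_m


def write_curve_tsv(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve as TSV with ``#`` header lines carrying metadata."""
    path = Path(path)
    lines = []
    if curve.calibration is not None:
        lines.append(f"# spring_constant_n_per_m\t{curve.calibration.spring_constant_n_per_m!r}")
        lines.append(f"# temperature_k\t{curve.calibration.temperature_k!r}")
        lines.append(f"# thermal_correction\t{curve.calibration.thermal_correction!r}")
    lines.append(f"# medium\t{curve.medium}")
    for key, val in curve.metadata.items():
        lines.append(f"# {key}\t{val}")
    lines.append("z_nm\tdeflection_nm\tsegment")
    for z, d, s in zip(curve.z_nm, curve.deflection_nm, curve.segment):
        lines.append(f"{z:.9g}\t{d:.9g}\t{s}")
    path.write_text("\n".join(lines) + "\n")


def read_curve_tsv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta: dict = {}
    rows: list[str] = []
    header: list[str] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append(line)
    if header is None or not rows:
        raise ValueError(f"no curve data found in {path}")
    data = pd.DataFrame([r.split("\t") for r in rows], columns=header)
    calib = None
    if "spring_constant_n_per_m" in meta:
        calib = CantileverCalibration(
            spring_constant_n_per_m=float(meta.pop("spring_constant_n_per_m")),
            temperature_k=float(meta.pop("temperature_k", 294.0)),
            thermal_correction=float(meta.pop("thermal_correction", 0.971)),
        )
    medium = meta.pop("medium", "PBS")
    return ForceCurve(
        z_nm=data["z_nm"].astype(float).to_numpy(),
        deflection_nm=data["deflection_nm"].astype(float).to_numpy(),
        segment=data["segment"].to_numpy(),
        medium=medium,
        calibration=calib,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# tip area function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TipAreaFunction:
    """Projected area ``A_c(h_c)`` of the indenter.

    In ``ideal-geometry`` mode the tip is a cone of half-angle ``theta_deg``:
    ``A_c = π·tan²θ·h_c²``.  In ``calibrated`` mode the standard area-function
    series ``A_c = C0·h² + C1·h + C2·h^½ + C3·h^¼ + …`` is evaluated with the
    supplied coefficients (h in nm, A in nm²).
    """

    theta_deg: float = 35.0
    coefficients: tuple[float, ...] | None = None
    source: str = "ideal-geometry"

    def __post_init__(self) -> None:
        if not 0 < self.theta_deg < 90:
            raise ValueError("tip half-angle must lie in (0°, 90°)")
        if self.source == "calibrated" and not self.coefficients:
            raise ValueError("calibrated area function requires coefficients")

    @property
    def k_geom(self) -> float:
        """Ideal-geometry prefactor π·tan²θ."""
        return float(np.pi * np.tan(np.radians(self.theta_deg)) ** 2)

    def area_nm2(self, h_c_nm: float) -> float:
        if h_c_nm < 0:
            raise ValueError("contact depth must be non-negative")
        if self.source == "ideal-geometry" or self.coefficients is None:
            return self.k_geom * h_c_nm**2
        exps = [2.0, 1.0] + [0.5**i for i in range(1, len(self.coefficients) - 1)]
        a = float(
            sum(c * h_c_nm**e for c, e in zip(self.coefficients, exps) if h_c_nm > 0 or e == 2.0)
        )
        if h_c_nm > 0 and a <= 0:
            raise ValueError("calibrated area function is non-positive at this depth")
        return a

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "theta_deg": self.theta_deg,
                    "coefficients": list(self.coefficients) if self.coefficients else None,
                    "source": self.source,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TipAreaFunction":
        obj = json.loads(Path(path).read_text())
        coeffs = obj.get("coefficients")
        return cls(
            theta_deg=float(obj["theta_deg"]),
            coefficients=tuple(coeffs) if coeffs else None,
            source=obj.get("source", "calibrated" if coeffs else "ideal-geometry"),
        )


def area_at_depth(area_fn: TipAreaFunction, h_c_nm: float) -> float:
    """Projected contact area in nm² at contact depth ``h_c`` (nm)."""
    return area_fn.area_nm2(h_c_nm)


# ---------------------------------------------------------------------------
# contact point
# ---------------------------------------------------------------------------


@dataclass
class ContactPointResult:
    z0_nm: float
    found: bool
    baseline_rms_nn: float
    baseline_coeffs: tuple[float, float]
    crossing_index: int | None = None


def _baseline_correct(z: np.ndarray, f: np.ndarray, baseline_fraction: float):
    nb = max(8, int(round(baseline_fraction * len(z))))
    nb = min(nb, len(z))
    coeffs = np.polyfit(z[:nb], f[:nb], 1)
    fc = f - np.polyval(coeffs, z)
    sd = float(np.std(fc[:nb]))
    return fc, sd, nb, (float(coeffs[0]), float(coeffs[1]))


def find_contact_point(
    curve: ForceCurve,
    threshold_sd: float = 5.0,
    baseline_fraction: float = 0.3,
    min_run: int = 5,
    exponent: float = 2.0,
    refine: bool = True,
) -> ContactPointResult:
    """Locate the tip–sample contact point on the approach segment.

    A linear baseline is fitted on the leading ``baseline_fraction`` of the
    approach; the candidate contact is the first sample whose baseline-corrected
    force stays above ``threshold_sd`` baseline standard deviations for
    ``min_run`` consecutive points.  The estimate is then refined by a
    two-regime fit: zero force before z₀ and a power law ``F = a·δ^m`` (with
    ``δ = (z − z₀) − d`` the deflection-corrected indentation) after z₀.

    Returns an explicit ``found=False`` result when no contact is detected.
    """
    z, d = curve.segment_arrays("approach")
    if len(z) < 16:
        raise ValueError("approach segment too short for contact detection")
    k = curve.spring_constant
    f = k * d
    fc, sd, nb, coeffs = _baseline_correct(z, f, baseline_fraction)
    scale = max(float(np.max(np.abs(fc))), 1e-12)
    thr = max(threshold_sd * sd, 1e-9 * scale)

    above = fc > thr
    crossing = None
    run = np.convolve(above.astype(int), np.ones(min_run, dtype=int), mode="valid")
    hits = np.nonzero(run == min_run)[0]
    if len(hits):
        crossing = int(hits[0])
    if crossing is None or crossing < 2:
        return ContactPointResult(float("nan"), False, sd, coeffs, None)

    # deflection above baseline; smoothed so its noise does not couple into
    # the indentation coordinate inside the fit (errors-in-variables bias)
    d_corr = fc / k
    if len(d_corr) > 31:
        d_corr = signal.savgol_filter(d_corr, 31, 2)

    def sse(z0: float) -> float:
        delta = (z - z0) - d_corr
        contact = delta > 0
        if contact.sum() < 4:
            return float(np.sum(fc**2))
        dl, fl = delta[contact], fc[contact]
        basis = dl**exponent
        denom = float(np.dot(basis, basis))
        a = float(np.dot(basis, fl)) / denom if denom > 0 else 0.0
        a = max(a, 0.0)
        resid = fl - a * basis
        return float(np.sum(resid**2) + np.sum(fc[~contact] ** 2))

    z0 = float(z[crossing])
    if refine:
        lo = float(z[max(nb - 1, 0)])
        hi = float(z[min(crossing + min_run, len(z) - 1)])
        if hi <= lo:
            hi = lo + 1e-9
        grid = np.linspace(lo, hi, 96)
        vals = [sse(g) for g in grid]
        i = int(np.argmin(vals))
        g_lo = grid[max(i - 1, 0)]
        g_hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(sse, bounds=(g_lo, g_hi), method="bounded",
                                       options={"xatol": 1e-6})
        z0 = float(res.x)
    return ContactPointResult(z0, True, sd, coeffs, crossing)


def to_force_and_separation(
    curve: ForceCurve, z0_nm: float, segment: str = "approach",
    smooth_window: int = 31,
) -> tuple[np.ndarray, np.ndarray]:
    """Indentation δ (nm) and force F (nN) relative to the contact point.

    ``F = k·(d − d_baseline)`` and ``δ = (z − z₀) − (d − d_baseline)``: the
    piezo travel corrected for the cantilever's own bending.  The deflection
    baseline is a line fitted on the pre-contact region (or its median when too
    few pre-contact points exist).

    Because the same deflection noise would otherwise enter both channels with
    opposite sign (an errors-in-variables coupling that attenuates any slope
    fitted to F(δ)), the deflection used for the *separation* correction is
    smoothed with a Savitzky–Golay filter of ``smooth_window`` points (order
    2); the force channel is left raw.  ``smooth_window ≤ 1`` disables this.
    """
    z, d = curve.segment_arrays(segment)
    zmin, zmax = float(np.min(z)), float(np.max(z))
    if not (zmin <= z0_nm <= zmax):
        raise ValueError(f"contact point {z0_nm} nm outside curve range [{zmin}, {zmax}] nm")
    k = curve.spring_constant
    pre = z < z0_nm
    if pre.sum() >= 8:
        coeffs = np.polyfit(z[pre], d[pre], 1)
        d_base = np.polyval(coeffs, z)
    else:
        d_base = np.full_like(z, np.median(d[pre]) if pre.any() else 0.0)
    d_rel = d - d_base
    force_nn = k * d_rel
    if smooth_window > 1 and len(d_rel) > smooth_window:
        win = smooth_window + 1 - smooth_window % 2  # force odd
        d_for_delta = signal.savgol_filter(d_rel, win, 2)
    else:
        d_for_delta = d_rel
    delta_nm = (z - z0_nm) - d_for_delta
    return delta_nm, force_nn


# ---------------------------------------------------------------------------
# stiffness, depth, moduli
# ---------------------------------------------------------------------------


@dataclass
class StiffnessFit:
    s_c_n_per_m: float
    exponent: float
    prefactor: float
    delta_max_nm: float
    r_squared: float
    residual_sd_nn: float


def contact_stiffness(
    delta_nm: Sequence[float],
    force_nn: Sequence[float],
    fit_fraction: float = 0.3,
    exponent: float | None = None,
) -> StiffnessFit:
    """Contact stiffness ``S_c = dF/dδ`` at maximum load.

    A power law ``F = a·δ^m`` is fitted over the top ``fit_fraction`` of the
    in-contact δ range and differentiated at δ_max.  With ``exponent=None`` the
    exponent is free (log–log least squares); a fixed exponent (e.g. 2 for an
    ideal cone) uses plain linear least squares on the corresponding basis.
    ``S_c`` is returned in N/m (≡ nN/nm).
    """
    if not 0 < fit_fraction <= 1:
        raise ValueError("fit_fraction must lie in (0, 1]")
    delta = np.asarray(delta_nm, dtype=float)
    force = np.asarray(force_nn, dtype=float)
    contact = delta > 0
    delta, force = delta[contact], force[contact]
    if len(delta) < 8:
        raise ValueError("need at least 8 in-contact points")
    order = np.argsort(delta)
    delta, force = delta[order], force[order]
    # monotonicity check after smoothing on a scale coarse enough to average
    # out point noise but fine enough to catch genuine non-monotonic segments
    win = int(np.clip(len(force) // 8, 5, 51))
    smooth = np.convolve(force, np.ones(win) / win, mode="valid")
    if len(smooth) > 2:
        frac_neg = float(np.mean(np.diff(smooth) < 0))
        if smooth[-1] <= smooth[0] or frac_neg > 0.45:
            raise ValueError("contact segment is not monotonically increasing after smoothing")

    d_max = float(delta[-1])
    cutoff = d_max * (1.0 - fit_fraction)
    sel = delta >= cutoff
    if sel.sum() < 4:
        sel = np.zeros_like(sel)
        sel[-4:] = True
    dl, fl = delta[sel], force[sel]

    if exponent is None:
        pos = fl > 0
        if pos.sum() < 4:
            raise ValueError("too few positive-force points for a free power-law fit")
        m, ln_a = np.polyfit(np.log(dl[pos]), np.log(fl[pos]), 1)
        a = float(np.exp(ln_a))
        m = float(m)
    else:
        m = float(exponent)
        basis = dl**m
        a = float(np.dot(basis, fl) / np.dot(basis, basis))
    pred = a * dl**m
    ss_res = float(np.sum((fl - pred) ** 2))
    ss_tot = float(np.sum((fl - np.mean(fl)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s_c = a * m * d_max ** (m - 1.0)
    if not np.isfinite(s_c) or s_c <= 0:
        raise ValueError("contact stiffness fit produced a non-positive slope")
    return StiffnessFit(
        s_c_n_per_m=float(s_c),
        exponent=m,
        prefactor=a,
        delta_max_nm=d_max,
        r_squared=r2,
        residual_sd_nn=float(np.sqrt(ss_res / max(len(fl) - 2, 1))),
    )


def contact_depth(h_max_nm: float, p_max_nn: float, s_c_n_per_m: float,
                  epsilon: float = EPSILON_CONE) -> float:
    """Oliver–Pharr contact depth ``h_c = h_max − ε·P_max/S_c`` (nm).

    nN / (N/m) = nm, so the mixed AFM units need no conversion factor.  A
    negative result is clipped to zero with a warning.
    """
    if s_c_n_per_m <= 0:
        raise ValueError("contact stiffness must be positive")
    h_c = h_max_nm - epsilon * p_max_nn / s_c_n_per_m
    if h_c < 0:
        warnings.warn("negative contact depth clipped to zero", stacklevel=2)
        return 0.0
    return float(h_c)


def reduced_modulus(s_c_n_per_m: float, a_c_nm2: float, beta: float = 1.0) -> float:
    """Reduced (composite) modulus ``E_r = √π/(2β) · S_c/√A_c`` in Pa.

    ``β`` is the indenter-shape factor (1.0226–1.085 in theory); the analysis
    convention here takes β = 1 by default.
    """
    if s_c_n_per_m <= 0 or a_c_nm2 <= 0:
        raise ValueError("stiffness and area must be positive")
    if not (beta == 1.0 or 1.0226 < beta < 1.085):
        raise ValueError("beta must be 1 or within (1.0226, 1.085)")
    a_m2 = a_c_nm2 * 1e-18
    return float(np.sqrt(np.pi) / (2.0 * beta) * s_c_n_per_m / np.sqrt(a_m2))


def sample_modulus(
    e_r_pa: float,
    nu_sample: float = 0.5,
    mode: str = "simplified",
    e_indenter_pa: float = 169e9,
    nu_indenter: float = 0.27,
) -> float:
    """Sample modulus from the reduced modulus.

    ``simplified`` assumes a rigid indenter relative to the sample:
    ``E_sample = (1 − ν²)·E_r`` — appropriate when E_indenter (169 GPa for a
    silicon tip) vastly exceeds the fibril modulus.  ``two_body`` solves the
    full relation ``1/E_r = (1−ν_s²)/E_s + (1−ν_i²)/E_i`` exactly.
    """
    if not 0 <= nu_sample <= 0.5:
        raise ValueError("sample Poisson ratio must lie in [0, 0.5]")
    if e_r_pa <= 0:
        raise ValueError("reduced modulus must be positive")
    if mode == "simplified":
        return (1.0 - nu_sample**2) * e_r_pa
    if mode == "two_body":
        indenter_term = (1.0 - nu_indenter**2) / e_indenter_pa
        inv = 1.0 / e_r_pa - indenter_term
        if inv <= 0:
            raise ValueError(
                "non-physical input: reduced modulus exceeds the indenter compliance limit"
            )
        return (1.0 - nu_sample**2) / inv
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# full-curve analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the indentation-modulus chain.

    Every physical assumption (ν_sample, ε, β, area-function source) is an
    explicit field and is echoed into each :class:`ContactAnalysis` so batch
    outputs are self-describing.
    """

    epsilon: float = EPSILON_CONE
    beta: float = 1.0
    deflection_smooth_window: int = 31
    nu_sample: float = 0.5
    mode: str = "simplified"
    e_indenter_pa: float = 169e9
    nu_indenter: float = 0.27
    fit_fraction: float = 0.3
    #: fixed at 2 to match the ideal-cone contact model the default area
    #: function assumes; set to None for a free power-law exponent
    stiffness_exponent: float | None = 2.0
    contact_threshold_sd: float = 5.0
    baseline_fraction: float = 0.3
    min_run: int = 5
    segment: str = "approach"


@dataclass
class ContactAnalysis:
    """Per-curve contact-mechanics result (invalid results carry a reason)."""

    valid: bool
    reason: str | None = None
    contact_point_nm: float = float("nan")
    h_max_nm: float = float("nan")
    p_max_nn: float = float("nan")
    s_c_n_per_m: float = float("nan")
    epsilon: float = float("nan")
    h_c_nm: float = float("nan")
    a_c_nm2: float = float("nan")
    beta: float = float("nan")
    e_r_pa: float = float("nan")
    nu_sample: float = float("nan")
    nu_indenter: float = float("nan")
    e_indenter_pa: float = float("nan")
    e_sample_pa: float = float("nan")
    fit_r_squared: float = float("nan")
    fit_residual_sd_nn: float = float("nan")
    baseline_rms_nn: float = float("nan")
    stiffness_exponent: float = float("nan")
    medium: str = ""
    config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = asdict(self)
        row.pop("config", None)
        return row


def analyze_curve(
    curve: ForceCurve,
    area_fn: TipAreaFunction | None = None,
    config: AnalysisConfig | None = None,
) -> ContactAnalysis:
    """Run the full chain on one curve and return a populated ContactAnalysis.

    Curves with no detectable contact are returned as ``valid=False`` (reason
    ``"no-contact"``) rather than raising, so batch runs can exclude them.
    """
    config = config or AnalysisConfig()
    area_fn = area_fn or TipAreaFunction()
    echo = asdict(config)
    echo["area_source"] = area_fn.source
    echo["theta_deg"] = area_fn.theta_deg
    try:
        cp = find_contact_point(
            curve,
            threshold_sd=config.contact_threshold_sd,
            baseline_fraction=config.baseline_fraction,
            min_run=config.min_run,
        )
    except ValueError as exc:
        return ContactAnalysis(valid=False, reason=f"contact-point: {exc}",
                               medium=curve.medium, config=echo)
    if not cp.found:
        return ContactAnalysis(valid=False, reason="no-contact", medium=curve.medium,
                               baseline_rms_nn=cp.baseline_rms_nn, config=echo)
    delta, force = to_force_and_separation(
        curve, cp.z0_nm, segment=config.segment,
        smooth_window=config.deflection_smooth_window)
    try:
        fit = contact_stiffness(delta, force, fit_fraction=config.fit_fraction,
                                exponent=config.stiffness_exponent)
    except ValueError as exc:
        return ContactAnalysis(valid=False, reason=f"stiffness: {exc}",
                               contact_point_nm=cp.z0_nm, medium=curve.medium, config=echo)
    h_max = fit.delta_max_nm
    p_max = fit.prefactor * h_max**fit.exponent  # smoothed load at max depth
    try:
        h_c = contact_depth(h_max, p_max, fit.s_c_n_per_m, epsilon=config.epsilon)
        a_c = area_at_depth(area_fn, h_c)
        e_r = reduced_modulus(fit.s_c_n_per_m, a_c, beta=config.beta)
        e_s = sample_modulus(e_r, nu_sample=config.nu_sample, mode=config.mode,
                             e_indenter_pa=config.e_indenter_pa,
                             nu_indenter=config.nu_indenter)
    except ValueError as exc:
        return ContactAnalysis(valid=False, reason=f"moduli: {exc}",
                               contact_point_nm=cp.z0_nm, medium=curve.medium, config=echo)
    return ContactAnalysis(
        valid=True,
        contact_point_nm=cp.z0_nm,
        h_max_nm=h_max,
        p_max_nn=p_max,
        s_c_n_per_m=fit.s_c_n_per_m,
        epsilon=config.epsilon,
        h_c_nm=h_c,
        a_c_nm2=a_c,
        beta=config.beta,
        e_r_pa=e_r,
        nu_sample=config.nu_sample,
        nu_indenter=config.nu_indenter,
        e_indenter_pa=config.e_indenter_pa,
        e_sample_pa=e_s,
        fit_r_squared=fit.r_squared,
        fit_residual_sd_nn=fit.residual_sd_nn,
        baseline_rms_nn=cp.baseline_rms_nn,
        stiffness_exponent=fit.exponent,
        medium=curve.medium,
        config=echo,
    )


def analyze_batch(
    curves: Sequence[ForceCurve],
    area_fn: TipAreaFunction | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Analyze many curves; one row per curve, invalid curves flagged."""
    rows = []
    for i, curve in enumerate(curves):
        res = analyze_curve(curve, area_fn=area_fn, config=config)
        row = res.as_row()
        row["curve_index"] = i
        rows.append(row)
    return pd.DataFrame(rows)
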