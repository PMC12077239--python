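"""CT-number calibration and density–modulus material mapping.

The material chain used throughout the pipeline is

    CT number (HU)
      --[phantom calibration, affine]-->  radiological density rho_CT (mgHA/cm^3)
      --[/1000, affine ash conversion]--> ash density rho_ash (g/cm^3)
      --[power law, region factors]-->    Young's modulus E (MPa)

Radiological density is carried in mgHA/cm^3 at the calibration stage
(matching scanner phantom conventions) and in g/cm^3 once it enters the
ash-density conversion; the /1000 conversion is the caller's responsibility
and is made explicit in :func:`rho_ct_to_rho_ash`'s contract.

Region-dependent modulus modification: sclerotic bone uses an *adaptive
factor* ``a_scl`` and lytic bone a *damage factor* ``d_lys``; both scale the
plain power law by ``(1 - factor)``.  ``a_scl`` may be negative (stiffening)
or positive (softening); ``d_lys`` only softens.  Factors of zero reproduce
the unmodified ("non-tuned") law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InvalidInputError

__all__ = [
    "CalibrationCurve",
    "DensityModulusLaw",
    "RegionFactors",
    "AsclLaw",
    "DEFAULT_CURVE",
    "DEFAULT_LAW",
    "fit_phantom_curve",
    "hu_to_rho_ct",
    "rho_ct_to_rho_ash",
    "rho_ash_to_modulus",
    "ascl_from_vscl",
]

#: Modulus regions recognised by :func:`rho_ash_to_modulus`.
REGIONS = ("plain", "sclerotic", "lytic")


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine CT-number <-> radiological-density map from a HA phantom scan.

    Forward model: ``HU = slope * rho_CT + intercept`` with ``rho_CT`` in
    mgHA/cm^3.  The default constants are the scanner calibration used for
    the standing-CT acquisitions this pipeline targets.
    """

    intercept_hu: float = 93.0710
    slope_hu_per_density: float = 1.0123
    plug_densities: tuple[float, ...] = ()
    plug_measured_hu: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept_hu) or not np.isfinite(self.slope_hu_per_density):
            raise InvalidInputError("calibration constants must be finite")
        if self.slope_hu_per_density <= 0:
            raise InvalidInputError("calibration slope must be positive")
        object.__setattr__(self, "plug_densities", tuple(float(v) for v in self.plug_densities))
        object.__setattr__(self, "plug_measured_hu", tuple(float(v) for v in self.plug_measured_hu))

    def hu_from_density(self, rho_ct):
        """Forward map: mgHA/cm^3 -> CT number."""
        return self.slope_hu_per_density * np.asarray(rho_ct, dtype=float) + self.intercept_hu

    def density_from_hu(self, hu):
        """Inverse map: CT number -> mgHA/cm^3 (no clamping)."""
        return (np.asarray(hu, dtype=float) - self.intercept_hu) / self.slope_hu_per_density

    def to_dict(self) -> dict:
        return {
            "intercept_hu": float(self.intercept_hu),
            "slope_hu_per_density": float(self.slope_hu_per_density),
            "plug_densities": [float(v) for v in self.plug_densities],
            "plug_measured_hu": [float(v) for v in self.plug_measured_hu],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            intercept_hu=float(d["intercept_hu"]),
            slope_hu_per_density=float(d["slope_hu_per_density"]),
            plug_densities=tuple(d.get("plug_densities", ())),
            plug_measured_hu=tuple(d.get("plug_measured_hu", ())),
        )


@dataclass(frozen=True)
class DensityModulusLaw:
    """Ash-density conversion plus the density–modulus power law.

    ``rho_ash = ash_slope * rho_CT + ash_intercept`` (both in g/cm^3) and
    ``E = coefficient * rho_ash ** exponent`` (E in MPa).  ``density_floor``
    clamps ash density from below so low-attenuation voxels inside the mesh
    (marrow spaces, rasterization slivers) receive a small positive modulus
    rather than zero or a negative value.
    """

    coefficient_mpa: float = 3378.0
    exponent: float = 1.52
    ash_slope: float = 0.8772
    ash_intercept_g_cm3: float = 0.07895
    density_floor_g_cm3: float = 0.01

    def __post_init__(self) -> None:
        if self.coefficient_mpa <= 0 or self.exponent <= 0:
            raise InvalidInputError("power-law coefficient and exponent must be positive")
        if self.density_floor_g_cm3 <= 0:
            raise InvalidInputError("density floor must be positive")


@dataclass(frozen=True)
class RegionFactors:
    """Adaptive (sclerotic) and damage (lytic) modulus factors.

    ``a_scl`` in [-1.00, 0.50]; ``d_lys`` in [0, 0.95].  ``RegionFactors(0, 0)``
    is the non-tuned model.
    """

    a_scl: float = 0.0
    d_lys: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.a_scl <= 0.5 + 1e-12):
            raise InvalidInputError(f"a_scl={self.a_scl} outside [-1.00, 0.50]")
        if not (0.0 - 1e-12 <= self.d_lys <= 0.95 + 1e-12):
            raise InvalidInputError(f"d_lys={self.d_lys} outside [0, 0.95]")


#: Default calibration curve (scanner phantom constants).
DEFAULT_CURVE = CalibrationCurve()
#: Default density–modulus law for equine MC3 bone.
DEFAULT_LAW = DensityModulusLaw()
#: Non-tuned material model.
UNTUNED = RegionFactors(0.0, 0.0)


@dataclass(frozen=True)
class AsclLaw:
    """Linear law mapping normalized sclerotic volume V_SCL to a_scl.

    The raw line ``slope * v_scl + intercept`` is clamped to the admissible
    adaptive-factor range.  The printed coefficients make the output
    extremely sensitive to V_SCL (the full clamp range is traversed over
    roughly 0.0015 in V_SCL), so the clamp is mandatory and both
    coefficients are configurable.
    """

    slope: float = 994.23
    intercept: float = -184.55
    clamp_lo: float = -1.00
    clamp_hi: float = 0.50

    def __call__(self, v_scl):
        return ascl_from_vscl(v_scl, self)

    def to_dict(self) -> dict:
        return {"slope": float(self.slope), "intercept": float(self.intercept)}


def fit_phantom_curve(plug_densities, plug_measured_hu) -> CalibrationCurve:
    """Fit the affine calibration curve from phantom plug measurements.

    Ordinary least squares of measured HU on known HA plug density.

    Parameters
    ----------
    plug_densities : sequence of float
        Known plug densities, mgHA/cm^3, strictly increasing, at least 2.
    plug_measured_hu : sequence of float
        Mean measured CT number per plug (same length, finite).
    """
    rho = np.asarray(plug_densities, dtype=float)
    hu = np.asarray(plug_measured_hu, dtype=float)
    if rho.ndim != 1 or rho.size < 2:
        raise InvalidInputError("at least two phantom plugs are required")
    if hu.shape != rho.shape:
        raise InvalidInputError("plug densities and measured HU must have equal length")
    if not np.all(np.isfinite(hu)) or not np.all(np.isfinite(rho)):
        raise InvalidInputError("plug values must be finite")
    if not np.all(np.diff(rho) > 0):
        raise InvalidInputError("plug densities must be strictly increasing")
    if np.ptp(rho) == 0:
        raise DegenerateFitError("zero variance in plug densities")
    slope, intercept = np.polyfit(rho, hu, 1)
    if slope <= 0:
        raise DegenerateFitError(f"non-positive fitted slope {slope}")
    return CalibrationCurve(
        intercept_hu=float(intercept),
        slope_hu_per_density=float(slope),
        plug_densities=tuple(rho),
        plug_measured_hu=tuple(hu),
    )


def hu_to_rho_ct(hu, curve: CalibrationCurve = DEFAULT_CURVE):
    """Convert CT number to radiological density (mgHA/cm^3). No clamping."""
    return curve.density_from_hu(hu)


def rho_ct_to_rho_ash(rho_ct_g_cm3, law: DensityModulusLaw = DEFAULT_LAW):
    """Convert radiological density to ash density, both in g/cm^3.

    The input must already be in g/cm^3 — converting from mgHA/cm^3
    (divide by 1000) is the caller's responsibility.  Output is clamped
    from below at ``law.density_floor_g_cm3``.
    """
    rho_ash = law.ash_slope * np.asarray(rho_ct_g_cm3, dtype=float) + law.ash_intercept_g_cm3
    return np.maximum(rho_ash, law.density_floor_g_cm3)


def rho_ash_to_modulus(
    rho_ash,
    law: DensityModulusLaw = DEFAULT_LAW,
    region: str = "plain",
    factors: RegionFactors = UNTUNED,
):
    """Young's modulus (MPa) from ash density (g/cm^3) with region factors.

    plain:      E = c * rho^p
    sclerotic:  E = (1 - a_scl) * c * rho^p
    lytic:      E = (1 - d_lys) * c * rho^p
    """
    if region not in REGIONS:
        raise InvalidInputError(f"unknown region {region!r}; expected one of {REGIONS}")
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho < law.density_floor_g_cm3 - 1e-12):
        raise InvalidInputError("rho_ash below the density floor; apply rho_ct_to_rho_ash first")
    base = law.coefficient_mpa * rho**law.exponent
    if region == "sclerotic":
        return (1.0 - factors.a_scl) * base
    if region == "lytic":
        return (1.0 - factors.d_lys) * base
    return base


def ascl_from_vscl(v_scl, law: AsclLaw = AsclLaw()):
    """Adaptive factor from normalized sclerotic volume, clamped to range."""
    v = np.asarray(v_scl, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise InvalidInputError("v_scl must be a fraction in [0, 1]")
    raw = law.slope * v + law.intercept
    out = np.clip(raw, law.clamp_lo, law.clamp_hi)
    return float(out) if out.ndim == 0 else out
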