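"""Tissue material model: bilinear elastoplastic parameters and property formulas.

Papaya skin and flesh are modelled as isotropic bilinear elastoplastic solids:
linear elastic with modulus ``E`` up to a yield stress ``sigma_y``, then linear
hardening with tangent modulus ``Et`` (``Et = 0`` recovers perfect plasticity).
Poisson's ratio is derived from moisture content, density from cylindrical
specimen geometry, and the full parameter sets are extracted from measured
stress--strain records or taken from the packaged measurement-level grid.

Units on this interface are as a lab would report them: stresses and moduli in
MPa, density in kg/m^3, lengths in mm, masses in g.  The solver converts to a
consistent mm-N-MPa-s system internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "MoistureMeasurement",
    "MaterialParams",
    "StressStrainRecord",
    "BilinearFit",
    "moisture_content",
    "poisson_from_moisture",
    "density_from_cylinder",
    "bilinear_stress",
    "hardening_modulus",
    "table_params",
    "property_levels",
    "fit_bilinear",
]

TISSUES = ("skin", "flesh")
LEVELS = ("min", "avg", "max")


class InvalidMeasurementError(ValueError):
    """A physical measurement violates its validity constraints."""


class InsufficientDataError(ValueError):
    """Too few data points to perform the requested extraction."""


@dataclass(frozen=True)
class MoistureMeasurement:
    """Oven-drying moisture measurement: wet mass ``wt1`` and dry mass ``wt2`` (g)."""

    wt1: float
    wt2: float

    def __post_init__(self) -> None:
        if not self.wt1 > 0:
            raise InvalidMeasurementError(f"wet mass must be positive, got {self.wt1}")
        if not (0 <= self.wt2 <= self.wt1):
            raise InvalidMeasurementError(
                f"dry mass must lie in [0, wet mass], got wt2={self.wt2}, wt1={self.wt1}"
            )


@dataclass(frozen=True)
class MaterialParams:
    """One tissue's bilinear elastoplastic parameter set.

    Parameters
    ----------
    E : float
        Elastic modulus (MPa).
    sigma_y : float
        Yield stress (MPa).  ``numpy.inf`` is accepted for a never-yielding
        (purely elastic) material.
    Et : float
        Post-yield tangent modulus (MPa).  ``Et == E`` is permitted only as the
        degenerate elastic limit (meaningful together with a very large
        ``sigma_y``); the hardening modulus is undefined there.
    nu : float
        Poisson's ratio, in [0, 0.5).
    rho : float
        Density (kg/m^3).
    """

    E: float
    sigma_y: float
    Et: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not self.sigma_y > 0:
            raise ValueError(f"sigma_y must be positive, got {self.sigma_y}")
        if not (0 <= self.Et <= self.E):
            raise ValueError(f"Et must satisfy 0 <= Et <= E, got Et={self.Et}, E={self.E}")
        if not (0 <= self.nu < 0.5):
            raise ValueError(f"nu must lie in [0, 0.5), got {self.nu}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")

    @property
    def hardening(self) -> float:
        """Linear isotropic hardening modulus H = E*Et/(E - Et) (MPa)."""
        return hardening_modulus(self.E, self.Et)

    @property
    def yield_strain(self) -> float:
        """Strain at first yield, sigma_y / E."""
        return self.sigma_y / self.E

    @property
    def rho_solver(self) -> float:
        """Density in the solver unit system (tonne/mm^3)."""
        return self.rho * 1e-12


@dataclass(frozen=True)
class StressStrainRecord:
    """A uniaxial engineering stress--strain record (strains dimensionless, stresses MPa)."""

    strains: np.ndarray
    stresses: np.ndarray

    def __post_init__(self) -> None:
        strains = np.asarray(self.strains, dtype=float)
        stresses = np.asarray(self.stresses, dtype=float)
        object.__setattr__(self, "strains", strains)
        object.__setattr__(self, "stresses", stresses)
        if strains.ndim != 1 or strains.shape != stresses.shape:
            raise ValueError("strains and stresses must be equal-length 1-D arrays")
        if strains.size < 2:
            raise InsufficientDataError("a stress-strain record needs at least 2 points")
        if strains[0] != 0:
            raise ValueError("strains must start at 0")
        if np.any(np.diff(strains) <= 0):
            raise ValueError("strains must be strictly increasing")


def moisture_content(m: MoistureMeasurement) -> float:
    """Moisture content in percent from an oven-drying measurement.

    MC = (wt1 - wt2) / wt1 * 100, where wt1 is the wet and wt2 the dry mass.
    """
    return (m.wt1 - m.wt2) / m.wt1 * 100.0


def poisson_from_moisture(mc: float) -> float:
    """Poisson's ratio from moisture content (percent).

    Linear blend between the fully dried value 0.1 and the fully fresh value
    0.5: ``nu = (0.5*MC + 0.1*(100 - MC)) / 100``.
    """
    if not (0 <= mc <= 100):
        raise ValueError(f"moisture content must lie in [0, 100] %, got {mc}")
    return (0.5 * mc + 0.1 * (100.0 - mc)) / 100.0


def density_from_cylinder(mass: float, diameter: float, height: float) -> float:
    """Density (g/cm^3) of a cylindrical specimen from mass (g) and dimensions (mm)."""
    if mass <= 0 or diameter <= 0 or height <= 0:
        raise ValueError("mass, diameter and height must all be positive")
    volume_mm3 = np.pi * (diameter / 2.0) ** 2 * height
    return mass / (volume_mm3 * 1e-3)  # mm^3 -> cm^3


def bilinear_stress(strain, p: MaterialParams):
    """Uniaxial stress (MPa) of the bilinear law at the given monotonic strain(s).

    Elastic branch ``E*eps`` up to the yield strain ``sigma_y/E``, then
    ``sigma_y + Et*(eps - sigma_y/E)``.  Accepts scalars or arrays.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps < 0):
        raise ValueError("negative strain is outside the uniaxial monotonic convention")
    eps_y = p.sigma_y / p.E
    sigma = np.where(eps <= eps_y, p.E * eps, p.sigma_y + p.Et * (eps - eps_y))
    return float(sigma) if np.isscalar(strain) else sigma


def hardening_modulus(E: float, Et: float) -> float:
    """Isotropic hardening modulus H = E*Et/(E - Et) for the radial-return map.

    H = 0 when Et = 0 (perfect plasticity).  Raises for Et >= E, where the
    bilinear law has no plastic branch.
    """
    if not 0 <= Et < E:
        raise ValueError(f"need 0 <= Et < E for a hardening modulus, got Et={Et}, E={E}")
    return E * Et / (E - Et)


def property_levels() -> dict:
    """The packaged min/avg/max measurement-level grid for skin and flesh."""
    text = resources.files("punctfem.data").joinpath("tissue_property_levels.json").read_text()
    return json.loads(text)


def table_params(tissue: str, level: str) -> MaterialParams:
    """Material parameters for one tissue at one measurement level.

    ``tissue`` is ``"skin"`` or ``"flesh"``; ``level`` is ``"min"``, ``"avg"``
    or ``"max"``, the printed extremes/mean of the measured property ranges.
    """
    if tissue not in TISSUES:
        raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    if level not in LEVELS:
        raise KeyError(f"unknown level {level!r}; expected one of {LEVELS}")
    grid = property_levels()[tissue]
    return MaterialParams(
        E=grid["E_MPa"][level],
        sigma_y=grid["sigma_y_MPa"][level],
        Et=grid["Et_MPa"][level],
        nu=grid["nu"][level],
        rho=grid["rho_kg_m3"][level],
    )


@dataclass(frozen=True)
class BilinearFit:
    """Result of fitting the bilinear law to a stress--strain record."""

    E: float
    sigma_y: float | None
    Et: float | None
    yield_detected: bool
    break_index: int | None = field(default=None)


def fit_bilinear(record: StressStrainRecord, linear_tol: float = 0.01) -> BilinearFit:
    """Extract (E, sigma_y, Et) from a uniaxial stress--strain record.

    The initial elastic modulus is the through-origin slope of the longest
    prefix whose least-squares residual stays below ``linear_tol`` times the
    maximum stress; the yield point is the first departure from that prefix,
    and ``Et`` is the least-squares slope of the remaining points.  The yield
    stress is taken at the intersection of the two fitted lines, so that the
    recovered parameters reproduce the record.

    If no departure is found the record is purely linear: ``E`` is returned and
    ``yield_detected`` is False.
    """
    eps = record.strains
    sig = record.stresses
    n = eps.size
    if n < 2:
        raise InsufficientDataError("need at least 2 points")
    tol = linear_tol * float(np.max(np.abs(sig)))
    if tol == 0:
        tol = 1e-12

    # longest prefix [0..k] fit through the origin with max residual < tol
    def prefix_slope(k: int) -> float:
        e, s = eps[: k + 1], sig[: k + 1]
        denom = float(np.dot(e, e))
        return float(np.dot(e, s)) / denom if denom > 0 else 0.0

    break_idx = None
    slope = prefix_slope(min(n - 1, 2))
    for k in range(2, n):
        cand = prefix_slope(k)
        resid = np.max(np.abs(sig[: k + 1] - cand * eps[: k + 1]))
        if resid > tol:
            break_idx = k
            break
        slope = cand

    if break_idx is None or break_idx > n - 2:
        return BilinearFit(E=slope, sigma_y=None, Et=None, yield_detected=False)

    # post-break least squares line sigma = c + Et*eps
    e2, s2 = eps[break_idx:], sig[break_idx:]
    A = np.vstack([np.ones_like(e2), e2]).T
    (c, Et), *_ = np.linalg.lstsq(A, s2, rcond=None)
    if slope - Et == 0:
        return BilinearFit(E=slope, sigma_y=None, Et=None, yield_detected=False)
    eps_y = c / (slope - Et)
    sigma_y = slope * eps_y
    if eps_y <= 0 or sigma_y <= 0:
        return BilinearFit(E=slope, sigma_y=None, Et=None, yield_detected=False)
    return BilinearFit(
        E=float(slope),
        sigma_y=float(sigma_y),
        Et=float(Et),
        yield_detected=True,
        break_index=int(break_idx),
    )
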