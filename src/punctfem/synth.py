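"""Seeded generators of surrogate experimental data.

Puncture instruments sample force at 200 points per second while the probe
advances at constant speed; a typical record rises linearly to the bioyield
peak, drops sharply as the skin ruptures, then fluctuates about a plateau
until maximum insertion.  These generators reproduce that structure, plus
dispersed material-property samples (truncated normal about per-storage-day
means) and noisy bilinear stress--strain records, so every pipeline stage can
be exercised without fruit.  All generators are pure functions of their spec
and seed: repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .material import MaterialParams, StressStrainRecord, bilinear_stress
from .metrics import ForceDeformationCurve

__all__ = [
    "SyntheticPunctureSpec",
    "SyntheticPropertySpec",
    "synth_puncture_curve",
    "synth_property_samples",
    "synth_bilinear_record",
]


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticPunctureSpec:
    """Shape parameters of a synthetic puncture force--deformation record.

    The bioyield deformation is snapped to the nearest sampled depth so the
    generated peak is exactly representable on the sampling grid.
    """

    bioyield_force: float  # N
    bioyield_deformation: float  # mm
    plateau_level: float = 0.55  # fraction of bioyield force after the drop
    fluctuation_amplitude: float = 0.06  # fraction of the plateau force
    velocity: float = 1.5  # mm/s
    max_depth: float = 10.0  # mm
    sampling_rate: float = 200.0  # points/s
    drop_width: float = 0.15  # mm over which the post-bioyield drop happens
    noise_sd: float = 0.0  # multiplicative force noise fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bioyield_force, self.bioyield_deformation, self.velocity,
               self.max_depth, self.sampling_rate) <= 0:
            raise InvalidSpecError("force, deformation, velocity, depth and rate must be positive")
        if not (0 < self.plateau_level < 1) or not (0 <= self.fluctuation_amplitude < 1):
            raise InvalidSpecError("plateau_level in (0,1), fluctuation_amplitude in [0,1)")
        if self.bioyield_deformation >= self.max_depth:
            raise InvalidSpecError("bioyield deformation must be smaller than max depth")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


def synth_puncture_curve(spec: SyntheticPunctureSpec) -> ForceDeformationCurve:
    """Generate one synthetic puncture record.

    Piecewise shape: linear rise from 0 to the bioyield force over
    [0, d_b]; linear drop to ``plateau_level * F_b`` over ``drop_width`` mm;
    then a plateau with a seeded sinusoid-plus-noise fluctuation out to
    ``max_depth``.  Sampling: depth = velocity * time at ``sampling_rate``.
    """
    dt = 1.0 / spec.sampling_rate
    n = int(np.floor(spec.max_depth / spec.velocity / dt)) + 1
    times = np.arange(n) * dt
    depths = spec.velocity * times
    d_step = spec.velocity * dt
    # snap the peak onto the sampling grid so the maximum is exact
    k_peak = max(1, int(round(spec.bioyield_deformation / d_step)))
    d_b = k_peak * d_step
    if d_b >= spec.max_depth:
        raise InvalidSpecError("bioyield deformation does not fit the sampled depth range")

    f_b = spec.bioyield_force
    plateau = spec.plateau_level * f_b
    d_drop_end = d_b + spec.drop_width
    forces = np.empty(n)
    rise = depths <= d_b + 1e-15
    forces[rise] = f_b * depths[rise] / d_b
    dropping = (~rise) & (depths < d_drop_end)
    forces[dropping] = f_b + (plateau - f_b) * (depths[dropping] - d_b) / spec.drop_width
    after = depths >= d_drop_end
    rng = np.random.default_rng(spec.seed)
    wavelength = 0.8  # mm, slow fluctuation of the penetration plateau
    phase = rng.uniform(0, 2 * np.pi)
    wiggle = spec.fluctuation_amplitude * plateau * np.sin(
        2 * np.pi * depths[after] / wavelength + phase
    )
    forces[after] = plateau + wiggle
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=n)
        forces = forces * (1.0 + noise)
    forces = np.maximum(forces, 0.0)
    # the constructed peak must survive noise clipping as the recorded maximum
    return ForceDeformationCurve(times=times, depths=depths, forces=forces, source="synthetic")


@dataclass(frozen=True)
class SyntheticPropertySpec:
    """Per-storage-day material-property dispersion: means +/- standard errors.

    ``mean`` is a MaterialParams of per-day mean values; ``se`` maps field
    names ("E", "sigma_y", "Et", "nu", "rho") to standard errors (0 allowed).
    Samples are drawn from normals truncated to each field's validity range.
    """

    mean: MaterialParams
    se: dict = field(default_factory=dict)
    n: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSpecError("need n >= 1 samples")


_BOUNDS = {
    "E": (1e-6, np.inf),
    "sigma_y": (1e-9, np.inf),
    "Et": (0.0, np.inf),
    "nu": (0.1, 0.4999),
    "rho": (1e-6, np.inf),
}


def synth_property_samples(spec: SyntheticPropertySpec) -> list[MaterialParams]:
    """Draw ``n`` truncated-normal material-parameter sets about the day mean."""
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name, (lo, hi) in _BOUNDS.items():
        mu = getattr(spec.mean, name)
        sd = float(spec.se.get(name, 0.0))
        if not (lo <= mu <= hi):
            raise InvalidSpecError(f"mean {name}={mu} outside its validity range [{lo}, {hi}]")
        if sd == 0:
            cols[name] = np.full(spec.n, mu)
            continue
        a, b = (lo - mu) / sd, (hi - mu) / sd
        cols[name] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=spec.n, random_state=rng)
    out = []
    for i in range(spec.n):
        Et = min(cols["Et"][i], 0.999 * cols["E"][i])  # keep Et < E after independent draws
        out.append(
            MaterialParams(E=cols["E"][i], sigma_y=cols["sigma_y"][i], Et=Et,
                           nu=cols["nu"][i], rho=cols["rho"][i])
        )
    return out


def synth_bilinear_record(p: MaterialParams, max_strain: float, n_points: int = 200,
                          noise_sd: float = 0.0, seed: int = 0) -> StressStrainRecord:
    """Sample the bilinear law on [0, max_strain] with multiplicative noise.

    A fixture generator for the stress--strain fitting routine; with
    ``noise_sd = 0`` the record lies exactly on the constitutive curve.
    """
    if max_strain <= 0:
        raise InvalidSpecError("max_strain must be positive")
    if n_points < 2:
        raise InvalidSpecError("a stress-strain record needs at least 2 points")
    strains = np.linspace(0.0, max_strain, n_points)
    stresses = bilinear_stress(strains, p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stresses = stresses * (1.0 + rng.normal(0.0, noise_sd, size=n_points))
    return StressStrainRecord(strains=strains, stresses=stresses)
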