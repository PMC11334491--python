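"""Synthetic contrast-enhancing lesion phantoms with analytically known geometry.

A phantom is a star-shaped solid whose boundary is a radial surface

    r(theta, phi) = R0 * (1 + sum_lm a_lm * Y_lm(theta, phi)),

where ``Y_lm`` are orthonormal *real* spherical harmonics without the
Condon-Shortley phase, ``R0`` is the base radius in cm and the ``a_lm`` are
dimensionless amplitudes.  An optional concentric spherical core of radius
``core_radius_fraction * R0`` emulates central necrosis: on contrast-enhanced
T1-weighted MRI viable tumor enhances brightly while the necrotic center does
not.  Volume and surface area of a phantom are available in closed form
(sphere) or by high-order angular quadrature, so every downstream image
analysis stage has an exact oracle.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

__all__ = [
    "PhantomSpec",
    "real_spherical_harmonic",
    "radial_function",
    "phantom_volume",
    "phantom_surface_area",
    "voxelize",
    "voxelize_labels",
    "simulate_series",
    "LABEL_BACKGROUND",
    "LABEL_CE",
    "LABEL_NECROSIS",
]

LABEL_BACKGROUND = 0
LABEL_CE = 1
LABEL_NECROSIS = 2

#: default intensity levels (background, necrotic core, enhancing rim), a.u.
DEFAULT_INTENSITY_LEVELS = (20.0, 45.0, 100.0)


class InvalidPhantomError(ValueError):
    """Raised when a phantom specification does not describe a valid solid."""


def real_spherical_harmonic(l: int, m: int, theta, phi, derivatives: bool = False):
    """Orthonormal real spherical harmonic without the Condon-Shortley phase.

    Conventions: ``m = 0`` gives the zonal harmonic; ``m > 0`` the
    cosine-type and ``m < 0`` the sine-type tesseral harmonic, each scaled
    by sqrt(2) so the set is orthonormal on the unit sphere.  ``theta`` is
    the polar angle (from +z), ``phi`` the azimuth.

    With ``derivatives=True`` returns ``(Y, dY/dtheta, dY/dphi)``.
    """
    if abs(m) > l:
        raise ValueError(f"order |m|={abs(m)} exceeds degree l={l}")
    am = abs(m)
    # scipy's complex Y_l^m carries the Condon-Shortley phase; (-1)^m removes it
    sign = (-1) ** am
    if derivatives:
        y, dy = sph_harm_y(l, am, theta, phi, diff_n=1)
        parts = (y, dy[..., 0], dy[..., 1]) if np.ndim(y) else (y, dy[0], dy[1])
        if m == 0:
            return tuple(np.real(p) for p in parts)
        if m > 0:
            return tuple(math.sqrt(2.0) * sign * np.real(p) for p in parts)
        return tuple(math.sqrt(2.0) * sign * np.imag(p) for p in parts)
    y = sph_harm_y(l, am, theta, phi)
    if m == 0:
        return np.real(y)
    if m > 0:
        return math.sqrt(2.0) * sign * np.real(y)
    return math.sqrt(2.0) * sign * np.imag(y)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and intensity description of one synthetic lesion.

    Parameters
    ----------
    base_radius : float
        Base radius ``R0`` of the radial surface, in cm.
    perturbation : sequence of (l, m, a_lm)
        Real-spherical-harmonic perturbation coefficients (dimensionless).
    core_radius_fraction : float
        Radius of the concentric necrotic core as a fraction of
        ``base_radius``; 0 means a solid (fully enhancing) lesion.
    center : tuple of float
        World coordinates of the lesion center, in mm.
    intensity_levels : tuple of float
        ``(background, necrotic, enhancing)`` intensities in arbitrary units,
        mimicking CE-T1w contrast (necrosis darker than rim, brighter than
        or equal to background).
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise.
    seed : int
        Seed for the voxelization noise.
    """

    base_radius: float
    perturbation: tuple = ()
    core_radius_fraction: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)
    intensity_levels: tuple = DEFAULT_INTENSITY_LEVELS
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "perturbation", tuple(tuple(p) for p in self.perturbation))
        if self.base_radius <= 0:
            raise InvalidPhantomError("base_radius must be positive")
        if not 0.0 <= self.core_radius_fraction < 1.0:
            raise InvalidPhantomError("core_radius_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidPhantomError("noise_sd must be non-negative")
        bg, nec, ce = self.intensity_levels
        if not (bg <= nec < ce):
            raise InvalidPhantomError(
                "intensity_levels must satisfy background <= necrotic < enhancing"
            )
        r = radial_function(self, *_dense_angular_grid())
        if np.min(r) <= 0:
            raise InvalidPhantomError("radial function is not strictly positive")
        if self.core_radius_fraction * self.base_radius >= np.min(r):
            raise InvalidPhantomError("necrotic core is not strictly inside the surface")

    def scaled(self, volume_factor: float, amplitude_factor: float = 1.0) -> "PhantomSpec":
        """Return a copy whose volume is ``volume_factor`` times this one's.

        Harmonic amplitudes may be rescaled independently to mimic the
        increase in surface irregularity observed after irradiation.
        """
        if volume_factor <= 0:
            raise ValueError("volume_factor must be positive")
        pert = tuple((l, m, a * amplitude_factor) for (l, m, a) in self.perturbation)
        return dataclasses.replace(
            self,
            base_radius=self.base_radius * volume_factor ** (1.0 / 3.0),
            perturbation=pert,
        )


def _dense_angular_grid(n_theta: int = 181, n_phi: int = 360):
    theta = np.linspace(1e-4, np.pi - 1e-4, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    return np.meshgrid(theta, phi, indexing="ij")


def radial_function(spec: PhantomSpec, theta, phi):
    """Evaluate r(theta, phi) in cm on arbitrary angular arrays."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape_fn = np.ones(np.broadcast(theta, phi).shape)
    for l, m, a in spec.perturbation:
        shape_fn = shape_fn + a * real_spherical_harmonic(int(l), int(m), theta, phi)
    return spec.base_radius * shape_fn


def _quadrature_grid(n_theta: int, n_phi: int):
    """Gauss-Legendre nodes in cos(theta) crossed with a uniform phi grid."""
    mu, w_mu = leggauss(n_theta)
    theta = np.arccos(mu)
    phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
    w_phi = 2 * np.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = np.broadcast_to((w_mu * w_phi)[:, None], T.shape)
    return T, P, W


def phantom_volume(spec: PhantomSpec, n_theta: int = 256, n_phi: int = 512) -> float:
    """Enclosed volume of the radial surface, in cm^3.

    V = (1/3) * integral of r(theta, phi)^3 over the solid angle, evaluated
    by Gauss-Legendre x uniform-azimuth quadrature.
    """
    T, P, W = _quadrature_grid(n_theta, n_phi)
    r = radial_function(spec, T, P)
    return float(np.sum(W * r**3) / 3.0)


def phantom_core_volume(spec: PhantomSpec) -> float:
    """Volume of the concentric necrotic core, in cm^3 (closed form)."""
    rc = spec.core_radius_fraction * spec.base_radius
    return 4.0 / 3.0 * math.pi * rc**3


def phantom_surface_area(spec: PhantomSpec, n_theta: int = 256, n_phi: int = 512) -> float:
    """Area of the outer radial surface, in cm^2.

    First fundamental form of a radial surface:
    dS = r * sqrt(r^2 + r_theta^2 + r_phi^2 / sin^2(theta)) dOmega.
    """
    T, P, W = _quadrature_grid(n_theta, n_phi)
    r = np.full(T.shape, float(spec.base_radius))
    r_t = np.zeros(T.shape)
    r_p = np.zeros(T.shape)
    for l, m, a in spec.perturbation:
        y, dyt, dyp = real_spherical_harmonic(int(l), int(m), T, P, derivatives=True)
        r = r + spec.base_radius * a * y
        r_t = r_t + spec.base_radius * a * dyt
        r_p = r_p + spec.base_radius * a * dyp
    sin_t = np.sin(T)
    integrand = r * np.sqrt(r**2 + r_t**2 + (r_p / sin_t) ** 2)
    return float(np.sum(W * integrand))


def _max_radius_mm(spec: PhantomSpec) -> float:
    r = radial_function(spec, *_dense_angular_grid())
    return float(np.max(r)) * 10.0


def _voxel_grid(spec: PhantomSpec, spacing, margin_voxels: int):
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,):
        raise ValueError("spacing must have three components (mm)")
    if np.any(spacing <= 0) or np.any(spacing > 5.0):
        raise ValueError("voxel spacing must lie in (0, 5] mm per axis")
    r_max = _max_radius_mm(spec)
    half_extent = r_max + margin_voxels * spacing
    n = np.ceil(2 * half_extent / spacing).astype(int) + 1
    origin = np.asarray(spec.center) - (n - 1) / 2.0 * spacing
    return spacing, n, origin


def _inside_masks(spec: PhantomSpec, spacing, n, origin):
    axes = [origin[k] + spacing[k] * np.arange(n[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = spec.center
    dx, dy, dz = X - cx, Y - cy, Z - cz
    rho = np.sqrt(dx**2 + dy**2 + dz**2)  # mm
    cos_t = np.divide(dz, rho, where=rho > 0, out=np.ones_like(rho))
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r_surface = radial_function(spec, theta, phi) * 10.0  # cm -> mm
    inside = rho <= r_surface
    core_radius_mm = spec.core_radius_fraction * spec.base_radius * 10.0
    if core_radius_mm > 0:
        core = (rho <= core_radius_mm) & inside
    else:
        core = np.zeros_like(inside)
    return inside, core


def voxelize_labels(spec: PhantomSpec, spacing, margin_voxels: int = 2):
    """Ground-truth label grid (0 background, 1 enhancing, 2 necrotic core).

    Voxel-center rule: a voxel belongs to the lesion iff its center lies
    inside the radial surface; it is necrotic iff additionally inside the
    core.  Returns ``(labels, spacing_mm, origin_mm)``.
    """
    spacing, n, origin = _voxel_grid(spec, spacing, margin_voxels)
    inside, core = _inside_masks(spec, spacing, n, origin)
    labels = np.zeros(tuple(n), dtype=np.uint8)
    labels[inside] = LABEL_CE
    labels[core] = LABEL_NECROSIS
    return labels, spacing, origin


def voxelize(spec: PhantomSpec, spacing, margin_voxels: int = 2, shape=None, origin=None):
    """Render the phantom into a CE-T1w-like intensity volume.

    The enhancing shell takes the ``enhancing`` intensity level, the core the
    ``necrotic`` level and everything else ``background``; Gaussian noise of
    ``spec.noise_sd`` is then added with the spec's seed (reproducible).

    By default the field of view is auto-sized to the phantom plus a
    two-voxel margin.  An explicit ``shape``/``origin`` pair may be given;
    a phantom that does not fit with the margin raises ``ValueError``.

    Returns an :class:`metmorph.segmentation.ImageVolume`.
    """
    from .segmentation import ImageVolume

    if shape is None:
        spacing, n, origin = _voxel_grid(spec, spacing, margin_voxels)
    else:
        spacing = np.asarray(spacing, dtype=float)
        n = np.asarray(shape, dtype=int)
        origin = np.asarray(origin, dtype=float)
        r_max = _max_radius_mm(spec)
        lo = np.asarray(spec.center) - r_max - margin_voxels * spacing
        hi = np.asarray(spec.center) + r_max + margin_voxels * spacing
        if np.any(lo < origin) or np.any(hi > origin + (n - 1) * spacing):
            raise ValueError("phantom exceeds the requested field of view")
    inside, core = _inside_masks(spec, spacing, n, origin)
    bg, nec, ce = spec.intensity_levels
    img = np.full(tuple(n), bg, dtype=float)
    img[inside] = ce
    img[core] = nec
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ImageVolume(intensities=img, spacing=tuple(spacing), origin=tuple(origin))


def simulate_series(
    spec: PhantomSpec,
    response_factors: Sequence[float],
    times: Sequence[float],
    amplitude_factors: Sequence[float] | None = None,
):
    """Longitudinal series of phantoms for one lesion.

    ``response_factors[k]`` scales the *volume* at ``times[k]`` (months)
    relative to the baseline spec, mimicking volumetric MRI follow-up every
    2-3 months after stereotactic radiotherapy.  The first entry is the
    baseline (typically factor 1 at a negative, pre-treatment time).
    ``amplitude_factors`` optionally rescales the harmonic amplitudes per
    timepoint to emulate the post-irradiation increase in surface
    irregularity.

    Returns a list of ``(time, PhantomSpec)`` pairs.
    """
    factors = list(response_factors)
    times = list(times)
    if not factors:
        raise ValueError("response_factors must be non-empty")
    if len(times) != len(factors):
        raise ValueError("times and response_factors must have equal length")
    if any(f <= 0 for f in factors):
        raise ValueError("response factors must be positive")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    if amplitude_factors is None:
        amplitude_factors = [1.0] * len(factors)
    if len(amplitude_factors) != len(factors):
        raise ValueError("amplitude_factors must match response_factors in length")
    return [
        (t, spec.scaled(f, amplitude_factor=g))
        for t, f, g in zip(times, factors, amplitude_factors)
    ]
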