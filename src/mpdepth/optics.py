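"""Model of in-focus and out-of-focus multiphoton excitation in scattering tissue.

A Gaussian beam focused to depth ``z0`` below the surface of a homogeneously
fluorescent, scattering medium generates fluorescence both in the focal volume
(from ballistic, unscattered photons) and throughout the illuminated cone
(from ballistic light above/below the focus, from scattered light, and from
their interaction).  This module evaluates, by numerical quadrature:

* the ballistic intensity profile ``I_b(z, rho)`` with a radially varying
  propagation distance through the scattering medium,
* the scattered-light intensity ``I_s(z, rho)`` from a small-angle
  beam-spread function,
* the in-focus fluorescence ``F_i`` and out-of-focus fluorescence ``F_oof``
  for photon order ``m = 2`` (two-photon) or ``m = 3`` (three-photon),
  including the binomial decomposition of ``(I_b + I_s)^m`` into ballistic,
  scattered, and cross terms,
* the signal-to-background ratio ``SBR = F_i / F_oof``, the contrast ratio
  ``CR = SBR / (1 + SBR)``, and the *balance depth* — the focal depth at
  which in-focus and out-of-focus fluorescence are equal (``CR = 0.5``),
  which bounds the useful imaging depth of two-photon microscopy.

All lengths are in micrometres; power is in arbitrary units (it cancels in
``SBR`` and ``CR``, which are homogeneous of degree zero in surface power).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e

__all__ = [
    "OpticalParameters",
    "QuadratureSettings",
    "FluorescenceBudget",
    "TermContribution",
    "DepthProfile",
    "QuadratureError",
    "propagation_distance",
    "ballistic_intensity",
    "scattered_spread",
    "scattered_intensity",
    "focal_power",
    "in_focus_fluorescence",
    "out_of_focus_fluorescence",
    "contrast_ratio",
    "balance_depth",
    "depth_profile",
    "fluorescence_origin_profile",
    "transverse_fluorescence_density",
]


class QuadratureError(RuntimeError):
    """Raised when a numerical integral fails an internal consistency check."""


@dataclass(frozen=True)
class OpticalParameters:
    """Physical constants of the beam/tissue model.

    Parameters
    ----------
    wavelength_um
        Excitation wavelength in vacuum (µm).  0.9 µm is typical for
        two-photon excitation of green indicators; 1.3 µm for three-photon.
    numerical_aperture
        NA of the focusing objective; the focusing half-angle is
        ``theta = asin(NA / n)``.
    refractive_index
        Bulk refractive index of the tissue (aqueous tissue ~1.33).
    anisotropy
        Scattering anisotropy ``g`` (mean cosine of the scattering angle);
        brain tissue is strongly forward scattering, ``g ~ 0.9``.  The
        small-angle spreading parameter is ``<Theta^2> = 2 (1 - g)``.
    scattering_length_um
        Mean free path ``l`` between scattering events; the attenuation
        coefficient is ``a = 1 / l``.  ~200 µm for ~900-nm light in cortex.
    focal_depth_um
        Depth ``z0`` of the ballistic focus below the tissue surface
        (``z = 0``, increasing into the tissue).
    surface_power
        Power ``P0`` entering the tissue (arbitrary units).
    photon_order
        Number of photons absorbed per excitation event: 2 or 3.
    exclusion_depth_um
        Half-thickness ``delta`` of the slab around ``z0`` counted as
        "in focus"; out-of-focus fluorescence is integrated over
        ``(0, z0 - delta) u (z0 + delta, z_max)``.  Defaults to ``l / 5``.
    width_convention
        Gaussian beam-width convention.  ``"standard"`` (default) uses
        ``w^2(z) = lambda ((z0 - z)^2 + zR^2) / (pi zR)``, under which the
        full-axis volume integral of the squared focal beam carrying power
        ``P`` equals ``pi P^2 / lambda`` exactly (the closed form used for
        the in-focus fluorescence).  ``"indexed"`` divides the width by an
        additional factor ``n`` (an alternative reading of the same
        convention); it changes absolute fluorescence yields but has only a
        mild effect on contrast-ratio curves.
    modality_constant
        Fluorophore concentration x excitation-efficiency factor ``C_m``,
        assumed uniform over the volume.  It cancels in SBR and CR.
    """

    wavelength_um: float = 0.9
    numerical_aperture: float = 0.8
    refractive_index: float = 1.33
    anisotropy: float = 0.9
    scattering_length_um: float = 200.0
    focal_depth_um: float = 450.0
    surface_power: float = 1.0
    photon_order: int = 2
    exclusion_depth_um: Optional[float] = None
    width_convention: str = "standard"
    modality_constant: float = 1.0

    def __post_init__(self) -> None:
        if not self.wavelength_um > 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.numerical_aperture < self.refractive_index:
            raise ValueError("need 0 < NA < refractive index")
        if not 0 <= self.anisotropy < 1:
            raise ValueError("anisotropy g must lie in [0, 1)")
        if not self.scattering_length_um > 0:
            raise ValueError("scattering length must be positive")
        if self.photon_order not in (2, 3):
            raise ValueError("photon order must be 2 or 3")
        if not self.surface_power > 0:
            raise ValueError("surface power must be positive")
        if self.width_convention not in ("standard", "indexed"):
            raise ValueError("width_convention must be 'standard' or 'indexed'")
        if not self.focal_depth_um > self.exclusion_depth:
            raise ValueError("focal depth must exceed the exclusion depth")
        if not self.exclusion_depth > 0:
            raise ValueError("exclusion depth must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def attenuation(self) -> float:
        """Scattering attenuation coefficient ``a = 1 / l`` (1/µm)."""
        return 1.0 / self.scattering_length_um

    @property
    def exclusion_depth(self) -> float:
        """In-focus exclusion half-depth ``delta`` (µm); default ``l / 5``."""
        if self.exclusion_depth_um is not None:
            return self.exclusion_depth_um
        return self.scattering_length_um / 5.0

    @property
    def half_angle(self) -> float:
        """Focusing half-angle ``theta = asin(NA / n)`` (radians)."""
        return math.asin(self.numerical_aperture / self.refractive_index)

    @property
    def tan_half_angle(self) -> float:
        return math.tan(self.half_angle)

    @property
    def mean_square_spread(self) -> float:
        """Small-angle spreading parameter ``<Theta^2> = 2 (1 - g)``."""
        return 2.0 * (1.0 - self.anisotropy)

    @property
    def rayleigh_length_um(self) -> float:
        """Rayleigh length ``zR = lambda n / (pi tan^2 theta)`` (µm)."""
        return (
            self.wavelength_um
            * self.refractive_index
            / (math.pi * self.tan_half_angle**2)
        )

    @property
    def width_prefactor(self) -> float:
        """Coefficient ``c`` in ``w^2(z) = c ((z0 - z)^2 + zR^2)`` (1/µm... µm)."""
        c = self.wavelength_um / (math.pi * self.rayleigh_length_um)
        if self.width_convention == "indexed":
            c /= self.refractive_index
        return c

    def beam_width_sq(self, z) -> np.ndarray:
        """Squared 1/e^2 ballistic beam width ``w^2(z)`` (µm^2)."""
        z = np.asarray(z, dtype=float)
        zr = self.rayleigh_length_um
        return self.width_prefactor * ((self.focal_depth_um - z) ** 2 + zr**2)

    @property
    def surface_width_um(self) -> float:
        """Beam 1/e^2 radius ``w0`` at the tissue surface (µm)."""
        return float(np.sqrt(self.beam_width_sq(0.0)))

    def replace(self, **changes) -> "OpticalParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class QuadratureSettings:
    """Node counts and truncations for the field integrals.

    The scattered-light integrand is a Gaussian in the surface coordinate
    ``eta`` whose width shrinks near the tissue surface; the eta axis is
    therefore tiled with uniform panels whose width tracks that scale
    (between ``eta_min_panels`` and ``eta_max_panels`` panels of
    ``eta_panel_points`` Gauss-Legendre nodes each).  Radial and axial
    integrals use composite Gauss-Legendre rules on panels aligned with the
    physical length scales of the integrand (ballistic width, scattered
    spread, exclusion depth).
    """

    radial_points: int = 160
    eta_panel_points: int = 16
    eta_min_panels: int = 8
    eta_max_panels: int = 160
    axial_points: int = 40
    radial_width_factor: float = 6.0
    eta_cutoff: float = 1e-8
    axial_max_scattering_lengths: float = 5.0

    def refined(self, factor: int) -> "QuadratureSettings":
        """A copy with node counts multiplied by ``factor`` (for oracle checks)."""
        return dataclasses.replace(
            self,
            radial_points=self.radial_points * factor,
            eta_panel_points=self.eta_panel_points * factor,
            eta_max_panels=self.eta_max_panels * factor,
            axial_points=self.axial_points * factor,
        )


#: Settings used by default throughout the package.
DEFAULT_QUADRATURE = QuadratureSettings()

#: Coarser settings for surveys and smoke tests (~1-2 % accuracy).
DRAFT_QUADRATURE = QuadratureSettings(
    radial_points=72,
    eta_panel_points=12,
    eta_min_panels=6,
    eta_max_panels=90,
    axial_points=20,
)


@dataclass(frozen=True)
class TermContribution:
    """One term of the binomial expansion of ``(I_b + I_s)^m``."""

    ballistic_power: int
    scattered_power: int
    value: float


@dataclass(frozen=True)
class FluorescenceBudget:
    """In-focus vs out-of-focus fluorescence at one focal depth.

    ``terms`` lists the binomial decomposition of the out-of-focus integral:
    for ``m = 2`` the pure-ballistic, cross, and pure-scattered terms
    (``F_b``, ``F_sb``, ``F_s``); for ``m = 3`` the four terms with binomial
    coefficients 1, 3, 3, 1.
    """

    in_focus: float
    out_of_focus: float
    terms: tuple
    focal_ballistic_power: float
    photon_order: int
    modality_constant: float = 1.0

    @property
    def sbr(self) -> float:
        """Signal-to-background ratio ``F_i / F_oof`` (inf if background-free)."""
        if self.out_of_focus == 0.0:
            return math.inf
        return self.in_focus / self.out_of_focus

    @property
    def contrast(self) -> float:
        """Contrast ratio ``CR = F_i / (F_i + F_oof)`` in [0, 1]."""
        total = self.in_focus + self.out_of_focus
        if total == 0.0:
            return 0.0
        return self.in_focus / total

    def term(self, ballistic_power: int) -> float:
        """Value of the term with the given ballistic exponent."""
        for t in self.terms:
            if t.ballistic_power == ballistic_power:
                return t.value
        raise KeyError(ballistic_power)


@dataclass(frozen=True)
class DepthProfile:
    """Contrast ratio evaluated on a grid of focal depths."""

    depths_um: np.ndarray
    contrast: np.ndarray
    sbr: np.ndarray
    in_focus: np.ndarray
    out_of_focus: np.ndarray
    balance_depth_um: Optional[float] = None


# ---------------------------------------------------------------------------
# quadrature helpers


@lru_cache(maxsize=64)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _panel_rule(edges: Sequence[float], n: int):
    """Composite Gauss-Legendre nodes/weights over consecutive panels."""
    x, w = _leggauss(n)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        nodes.append(0.5 * (hi + lo) + half * x)
        weights.append(half * w)
    return np.concatenate(nodes), np.concatenate(weights)


def _uniform_panels(lo: float, hi: float, n_panels: int):
    return np.linspace(lo, hi, n_panels + 1)


# ---------------------------------------------------------------------------
# field quantities


def propagation_distance(z, rho, z0, half_angle):
    """Path length ``s(z, rho) = z sqrt(1 + rho^2 / (z0 - z)^2)`` through tissue.

    The implied ray slope ``rho / |z0 - z|`` is capped at ``tan(half_angle)``
    — no illumination ray exceeds the aperture half-angle — which keeps the
    path length finite for every ``z`` including the focal plane, where the
    uncapped expression diverges for ``rho > 0``.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be nonnegative")
    if np.any(rho < 0):
        raise ValueError("radius rho must be nonnegative")
    tan_t = math.tan(half_angle)
    denom = np.abs(z0 - z)
    safe = np.where(denom > 0, denom, 1.0)
    slope = np.where(denom > 0, rho / safe, np.where(rho > 0, np.inf, 0.0))
    slope = np.minimum(slope, tan_t)
    out = z * np.sqrt(1.0 + slope**2)
    return out if out.shape else float(out)


def ballistic_intensity(z, rho, params: OpticalParameters):
    """Ballistic (unscattered) intensity ``I_b(z, rho)`` (power/µm^2).

    A Gaussian beam of 1/e^2 width ``w(z)`` carrying surface power ``P0``,
    attenuated by scattering along the radially varying propagation distance:
    ``I_b = (2 P0 / pi w^2) exp(-2 rho^2 / w^2) exp(-a s(z, rho))``.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be nonnegative")
    if np.any(rho < 0):
        raise ValueError("radius rho must be nonnegative")
    w2 = params.beam_width_sq(z)
    s = propagation_distance(z, rho, params.focal_depth_um, params.half_angle)
    out = (
        (2.0 * params.surface_power / (math.pi * w2))
        * np.exp(-2.0 * rho**2 / w2)
        * np.exp(-params.attenuation * np.asarray(s))
    )
    return out if np.asarray(out).shape else float(out)


def scattered_spread(z, rho, params: OpticalParameters):
    """Normalized beam-spread density ``h(z, rho)`` (1/µm^2) of scattered light.

    Small-angle scattering diffuses an initially on-axis ray into a Gaussian
    ``h = (3n / (pi a z^3 <Theta^2>)) exp(-3 n rho^2 / (a z^3 <Theta^2>))``
    that integrates to one over the transverse plane at every depth.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(z <= 0):
        raise ValueError("h(z, rho) is undefined at the surface; need z > 0")
    if np.any(rho < 0):
        raise ValueError("radius rho must be nonnegative")
    n = params.refractive_index
    scale = params.attenuation * z**3 * params.mean_square_spread
    out = (3.0 * n / (math.pi * scale)) * np.exp(-3.0 * n * rho**2 / scale)
    return out if np.asarray(out).shape else float(out)


def _eta_rule(z: float, params: OpticalParameters, quad: QuadratureSettings):
    """Quadrature rule over the surface coordinate eta for the scattered field.

    The phi integral of the beam-spread Gaussian has already been carried out
    analytically (it yields a Bessel ``I0`` factor), so the remaining eta
    integrand contains a Gaussian of 1/e half-width ``sigma_s / |c_z|`` with
    ``sigma_s = sqrt(a z^3 <Theta^2> / 3n)`` and ``c_z = (z0 - z)/z0``; panel
    widths are chosen to resolve it.
    """
    w0 = params.surface_width_um
    eta_max = w0 * math.sqrt(math.log(1.0 / quad.eta_cutoff) / 2.0)
    c = abs(params.focal_depth_um - z) / params.focal_depth_um
    sigma_s = math.sqrt(
        params.attenuation * z**3 * params.mean_square_spread
        / (3.0 * params.refractive_index)
    )
    if c > 0 and sigma_s > 0:
        n_panels = int(math.ceil(eta_max / (4.0 * sigma_s / c)))
    else:
        n_panels = quad.eta_min_panels
    n_panels = int(np.clip(n_panels, quad.eta_min_panels, quad.eta_max_panels))
    edges = _uniform_panels(0.0, eta_max, n_panels)
    return _panel_rule(edges, quad.eta_panel_points)


def scattered_intensity(
    z,
    rho,
    params: OpticalParameters,
    quad: QuadratureSettings = DEFAULT_QUADRATURE,
):
    """Scattered-light intensity ``I_s(z, rho)`` (power/µm^2).

    Each surface annulus of the incident Gaussian beam launches rays that
    scatter with probability ``1 - exp(-a s0)`` over their path
    ``s0 = z sqrt(1 + eta^2 / z0^2)`` and spread around the unscattered ray
    position ``(z0 - z)/z0 * eta`` according to the beam-spread function.
    The azimuthal part of the surface integral is analytic (a modified
    Bessel function); the remaining radial surface integral is evaluated by
    composite Gauss-Legendre quadrature (see :class:`QuadratureSettings`).
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    scalar_in = np.asarray(rho).ndim == 0
    z = float(z)
    if z <= 0:
        raise ValueError("scattered light is undefined at the surface; need z > 0")
    if np.any(rho_arr < 0):
        raise ValueError("radius rho must be nonnegative")
    a = params.attenuation
    if a == 0.0:
        out = np.zeros_like(rho_arr)
        return float(out[0]) if scalar_in else out

    z0 = params.focal_depth_um
    w0sq = params.beam_width_sq(0.0)
    eta, wq = _eta_rule(z, params, quad)
    s0 = z * np.sqrt(1.0 + eta**2 / z0**2)
    beta = (
        3.0 * params.refractive_index
        / (a * s0**3 * params.mean_square_spread)
    )
    envelope = (
        (4.0 * params.surface_power / (math.pi * w0sq))
        * beta
        * np.exp(-2.0 * eta**2 / w0sq)
        * (-np.expm1(-a * s0))
        * eta
        * wq
    )
    ca = abs(z0 - z) / z0
    r = rho_arr[:, None]
    gauss = np.exp(-beta * (r - ca * eta) ** 2) * i0e(2.0 * beta * r * ca * eta)
    out = gauss @ envelope
    return float(out[0]) if scalar_in else out


# ---------------------------------------------------------------------------
# transverse (per-depth) integrals


def _radial_rule(z: float, params: OpticalParameters, quad: QuadratureSettings):
    """Radial quadrature panels covering ballistic and scattered length scales."""
    w = float(np.sqrt(params.beam_width_sq(z)))
    scales = [w]
    if z > 0 and params.attenuation > 0:
        sigma_s = math.sqrt(
            params.attenuation * z**3 * params.mean_square_spread
            / (3.0 * params.refractive_index)
        )
        scales.append(sigma_s)
    k = quad.radial_width_factor
    edges = sorted({0.0} | {k * s for s in scales})
    # drop panels narrower than 2% of the widest scale (degenerate)
    cleaned = [edges[0]]
    for e in edges[1:]:
        if e - cleaned[-1] > 0.02 * edges[-1]:
            cleaned.append(e)
    return _panel_rule(cleaned, quad.radial_points)


def transverse_fluorescence_density(
    z: float,
    params: OpticalParameters,
    quad: QuadratureSettings = DEFAULT_QUADRATURE,
) -> dict:
    """Per-depth fluorescence line density of each binomial term (power^m/µm).

    Returns a mapping from ballistic exponent ``k`` to
    ``C(m, k) * 2 pi Int I_b^k I_s^(m-k) rho d rho`` times the modality
    constant; the total density is their sum.
    """
    m = params.photon_order
    rho, wq = _radial_rule(z, params, quad)
    ib = ballistic_intensity(z, rho, params)
    if z > 0 and params.attenuation > 0:
        isc = scattered_intensity(z, rho, params, quad)
    else:
        isc = np.zeros_like(rho)
    out = {}
    for k in range(m, -1, -1):
        coeff = math.comb(m, k)
        integrand = ib**k * isc ** (m - k) * rho
        out[k] = (
            params.modality_constant * coeff * 2.0 * math.pi * float(integrand @ wq)
        )
    return out


def focal_power(
    params: OpticalParameters, quad: QuadratureSettings = DEFAULT_QUADRATURE
) -> float:
    """Scattering-attenuated ballistic power reaching the focal plane.

    ``P_z0 = 2 pi Int I_b(z0, rho) rho d rho``.  Evaluated pointwise the
    integrand is singular at the focal plane (the ray-slope factor in the
    propagation distance diverges), but the transverse power integral has a
    removable singularity: changing variables to the surface (ray-entry)
    radius ``eta = rho z0 / (z0 - z)`` and letting ``z -> z0`` gives

    ``P_z0 = (4 P0 / w0'^2) Int exp(-2 eta^2 / w0'^2)
             exp(-a z0 sqrt(1 + eta^2 / z0^2)) eta d eta``

    with ``w0' = sqrt(c) z0`` the geometric surface width of the focal cone
    — each ray is attenuated along its own cone path, weighted by the
    surface Gaussian.  With ``a = 0`` this is exactly ``P0``.
    """
    z0 = params.focal_depth_um
    a = params.attenuation
    w0 = math.sqrt(params.width_prefactor) * z0
    eta_max = w0 * math.sqrt(math.log(1.0 / quad.eta_cutoff) / 2.0)
    eta, wq = _panel_rule([0.0, eta_max], quad.radial_points)
    s0 = z0 * np.sqrt(1.0 + eta**2 / z0**2)
    integrand = (
        (4.0 * params.surface_power / w0**2)
        * np.exp(-2.0 * eta**2 / w0**2)
        * np.exp(-a * s0)
        * eta
    )
    return float(integrand @ wq)


def in_focus_fluorescence(
    params: OpticalParameters, quad: QuadratureSettings = DEFAULT_QUADRATURE
) -> float:
    """Total in-focus fluorescence ``F_i`` (model units).

    Defined as the full-axis volume integral of the m-th power of an
    unscattered Gaussian focus carrying the attenuated focal power ``P_z0``:
    ``F_i = pi P^2 / lambda`` for two-photon excitation and
    ``F_i = 2 P^3 / (3 pi c^2 zR^3)`` for three-photon excitation, where
    ``c`` is the beam-width prefactor (``w^2 = c ((z-z0)^2 + zR^2)``).
    """
    p = focal_power(params, quad)
    c = params.width_prefactor
    zr = params.rayleigh_length_um
    if params.photon_order == 2:
        # equals pi P^2 / lambda under the "standard" width convention
        return params.modality_constant * p**2 / (c * zr)
    return params.modality_constant * 2.0 * p**3 / (3.0 * math.pi * c**2 * zr**3)


def _axial_rules(params: OpticalParameters, quad: QuadratureSettings):
    """Axial panels over the out-of-focus volume (0, z0-d) u (z0+d, z_max)."""
    z0 = params.focal_depth_um
    d = params.exclusion_depth
    z_max = z0 + quad.axial_max_scattering_lengths * params.scattering_length_um
    top = z0 - d
    lower_edges = [0.0, 0.35 * top, 0.7 * top, 0.9 * top, top]
    # below the focus the density decays like 1/(z - z0)^2: geometric panels
    upper_edges = [z0 + d]
    u = 2.0 * d
    while z0 + u < z_max:
        upper_edges.append(z0 + u)
        u *= 2.0
    upper_edges.append(z_max)
    zs_lo, w_lo = _panel_rule(lower_edges, quad.axial_points)
    zs_hi, w_hi = _panel_rule(upper_edges, quad.axial_points)
    return np.concatenate([zs_lo, zs_hi]), np.concatenate([w_lo, w_hi])


def out_of_focus_fluorescence(
    params: OpticalParameters, quad: QuadratureSettings = DEFAULT_QUADRATURE
) -> FluorescenceBudget:
    """Out-of-focus fluorescence and its ballistic/scattered decomposition.

    Integrates ``C_m (I_b + I_s)^m`` over tissue depths outside the in-focus
    slab and over the transverse plane.  Returns a
    :class:`FluorescenceBudget` whose ``terms`` decompose the total by
    ballistic exponent; for two-photon excitation these are the ``F_b``,
    ``F_sb`` (cross), and ``F_s`` contributions.
    """
    m = params.photon_order
    zs, wz = _axial_rules(params, quad)
    totals = {k: 0.0 for k in range(m, -1, -1)}
    for z, w in zip(zs, wz):
        dens = transverse_fluorescence_density(float(z), params, quad)
        for k, v in dens.items():
            totals[k] += w * v
    terms = tuple(
        TermContribution(ballistic_power=k, scattered_power=m - k, value=totals[k])
        for k in range(m, -1, -1)
    )
    return FluorescenceBudget(
        in_focus=in_focus_fluorescence(params, quad),
        out_of_focus=float(sum(totals.values())),
        terms=terms,
        focal_ballistic_power=focal_power(params, quad),
        photon_order=m,
        modality_constant=params.modality_constant,
    )


def contrast_ratio(
    params: OpticalParameters, quad: QuadratureSettings = DEFAULT_QUADRATURE
) -> FluorescenceBudget:
    """Fluorescence budget with SBR and CR at the configured focal depth.

    ``CR = F_i / (F_i + F_oof)`` is invariant under scaling of the surface
    power and of the modality constant (both numerator and denominator are
    homogeneous of degree ``m`` in power).
    """
    return out_of_focus_fluorescence(params, quad)


def depth_profile(
    params: OpticalParameters,
    depths_um: Sequence[float],
    quad: QuadratureSettings = DEFAULT_QUADRATURE,
) -> DepthProfile:
    """Evaluate the contrast ratio over a grid of focal depths."""
    depths = np.asarray(depths_um, dtype=float)
    if depths.ndim != 1 or len(depths) == 0:
        raise ValueError("depths must be a nonempty 1-D sequence")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly ascending")
    budgets = [contrast_ratio(params.replace(focal_depth_um=float(z)), quad) for z in depths]
    cr = np.array([b.contrast for b in budgets])
    prof = DepthProfile(
        depths_um=depths,
        contrast=cr,
        sbr=np.array([b.sbr for b in budgets]),
        in_focus=np.array([b.in_focus for b in budgets]),
        out_of_focus=np.array([b.out_of_focus for b in budgets]),
        balance_depth_um=None,
    )
    if cr[0] > 0.5 and cr[-1] < 0.5:
        bal = balance_depth(params, depths, quad, _profile=prof)
        prof = dataclasses.replace(prof, balance_depth_um=bal)
    return prof


def balance_depth(
    params: OpticalParameters,
    z_range: Sequence[float],
    quad: QuadratureSettings = DEFAULT_QUADRATURE,
    _profile: Optional[DepthProfile] = None,
) -> Optional[float]:
    """Focal depth at which in-focus and out-of-focus fluorescence are equal.

    Samples ``CR(z0)`` on ``z_range`` (ascending, within the tissue), checks
    that the sampled curve is monotone decreasing (a non-monotone curve
    indicates quadrature failure), and refines the ``CR = 0.5`` crossing by
    bracketed bisection.  Returns ``None`` if ``CR > 0.5`` over the whole
    range (no balance depth: the background never catches the signal).
    """
    zs = np.asarray(z_range, dtype=float)
    if zs.ndim != 1 or len(zs) < 2:
        raise ValueError("z_range must contain at least two depths")
    if np.any(np.diff(zs) <= 0):
        raise ValueError("z_range must be strictly ascending")
    if zs[0] <= params.exclusion_depth:
        raise ValueError("z_range must lie below the exclusion depth")

    def cr_at(z: float) -> float:
        return contrast_ratio(params.replace(focal_depth_um=float(z)), quad).contrast

    if _profile is not None and np.array_equal(_profile.depths_um, zs):
        cr = _profile.contrast
    else:
        cr = np.array([cr_at(z) for z in zs])
    if np.any(np.diff(cr) > 5e-3):
        raise QuadratureError(
            "sampled contrast-ratio curve is not monotone decreasing; "
            "increase quadrature resolution"
        )
    if np.all(cr > 0.5):
        return None
    if cr[0] < 0.5:
        raise ValueError("z_range does not bracket the CR = 0.5 crossing from above")
    i = int(np.argmax(cr < 0.5))
    lo, hi = float(zs[i - 1]), float(zs[i])
    return float(brentq(lambda z: cr_at(z) - 0.5, lo, hi, xtol=1.0))


def fluorescence_origin_profile(
    params: OpticalParameters,
    z_grid: Sequence[float],
    quad: QuadratureSettings = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """Depth profile of generated fluorescence, normalized to the focal plane.

    For each tissue depth ``z`` in ``z_grid`` the transverse integral of
    ``(I_b + I_s)^m`` is evaluated and divided by its value at ``z = z0``;
    the result is 1 at the focal plane and, for three-photon excitation, far
    smaller away from it than for two-photon excitation.
    """
    zs = np.asarray(z_grid, dtype=float)
    if np.any(zs < 0):
        raise ValueError("tissue depths must be nonnegative")
    ref = sum(
        transverse_fluorescence_density(params.focal_depth_um, params, quad).values()
    )
    vals = np.array(
        [sum(transverse_fluorescence_density(float(z), params, quad).values()) for z in zs]
    )
    return vals / ref
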