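"""Red-blood-cell shape and membrane-material closed forms.

The resting red cell is a biconcave disc; its surface is described by the
Evans-Fung parametrization

    z(x, y) = +/- D0 * sqrt(1 - 4 r^2 / D0^2)
              * (a0 + a1 * r^2/D0^2 + a2 * r^4/D0^4),   r^2 = x^2 + y^2,

with diameter D0 = 7.82 um and thickness coefficients a0 = 0.0518,
a1 = 2.0026, a2 = -4.491.  The membrane is modelled as a Kelvin-Voigt
viscoelastic solid (spring and dashpot in parallel): shear modulus
G = E / (2 (1 + v)), relaxation time tau = eta / G, and creep strain under
a step stress sigma0 of ``(sigma0/G) * (1 - exp(-t/tau))``.  A parallel-
plate shear box relates the moving-plate speed to the applied stress via
``v = tau * gap / mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeParams",
    "MembraneParams",
    "biconcave_z",
    "contour_perimeter",
    "plate_velocity",
    "membrane_constants",
    "creep_strain",
]


@dataclass(frozen=True)
class ShapeParams:
    """Biconcave-disc shape constants: diameter D0 (um) and the
    dimensionless thickness coefficients a0, a1, a2."""

    D0: float = 7.82
    a0: float = 0.0518
    a1: float = 2.0026
    a2: float = -4.491

    def __post_init__(self) -> None:
        if not self.D0 > 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")


@dataclass(frozen=True)
class MembraneParams:
    """Membrane material and medium properties (SI units).

    E: Young's modulus (Pa); v: Poisson's ratio; eta_membrane: membrane
    dynamic viscosity (Pa s); densities in kg/m^3; medium viscosities in
    Pa s.
    """

    E: float = 500.0
    v: float = 0.45
    eta_membrane: float = 0.022
    density_membrane: float = 1090.0
    density_intracellular: float = 1060.0
    density_extracellular: float = 1060.0
    viscosity_intracellular: float = 0.006
    viscosity_extracellular: float = 0.0012

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0 <= self.v < 0.5:
            raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {self.v}")
        if not self.eta_membrane > 0:
            raise ValueError("membrane viscosity must be positive")


def _radial2(x, y, shape: ShapeParams):
    return (np.asarray(x, dtype=float) ** 2 + np.asarray(y, dtype=float) ** 2) / shape.D0**2


def biconcave_z(x, y, shape: ShapeParams | None = None):
    """Upper-surface height z (um) of the biconcave disc at (x, y) in um.

    The surface is symmetric under z -> -z; this returns the positive
    branch.  Points beyond the rim radius D0/2 are rejected.
    """
    if shape is None:
        shape = ShapeParams()
    rho2 = _radial2(x, y, shape)  # (r/D0)^2
    if np.any(rho2 > 0.25 * (1 + 1e-12)):
        raise ValueError("point lies outside the cell rim (x^2 + y^2 > (D0/2)^2)")
    rho2 = np.minimum(rho2, 0.25)
    thickness = shape.a0 + shape.a1 * rho2 + shape.a2 * rho2**2
    return shape.D0 * np.sqrt(1.0 - 4.0 * rho2) * thickness


def contour_perimeter(shape: ShapeParams | None = None, n_samples: int = 4096) -> float:
    """Arc length (um) of the closed x-z cross-section contour.

    The meridional section through the symmetry axis consists of the upper
    branch z(x) for x in [-D0/2, D0/2] and its mirror image; the two
    branches meet at the rim where z = 0.  The length is computed by dense
    polyline integration and converges from below as ``n_samples`` grows.
    """
    if shape is None:
        shape = ShapeParams()
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64 for a meaningful contour")
    x = np.linspace(-shape.D0 / 2.0, shape.D0 / 2.0, n_samples)
    z = biconcave_z(x, 0.0, shape)
    upper = float(np.sum(np.hypot(np.diff(x), np.diff(z))))
    return 2.0 * upper


def plate_velocity(tau: float, gap: float, viscosity: float) -> float:
    """Moving-plate speed (m/s) producing shear stress ``tau`` (Pa) in a
    parallel-plate gap: ``v = tau * gap / viscosity``."""
    if tau < 0:
        raise ValueError(f"shear stress must be non-negative, got {tau}")
    if not gap > 0:
        raise ValueError(f"plate gap must be positive, got {gap}")
    if not viscosity > 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    return tau * gap / viscosity


def membrane_constants(m: MembraneParams | None = None) -> tuple[float, float]:
    """Kelvin-Voigt derived constants: (shear modulus G in Pa,
    relaxation time eta/G in s)."""
    if m is None:
        m = MembraneParams()
    G = m.E / (2.0 * (1.0 + m.v))
    return G, m.eta_membrane / G


def creep_strain(sigma0: float, m: MembraneParams | None = None, t: float = 0.0):
    """Kelvin-Voigt creep strain under a step stress sigma0 (Pa) at time t (s).

    ``(sigma0/G) * (1 - exp(-t/tau))``: zero at t = 0, monotonically rising
    to the elastic asymptote sigma0/G.
    """
    if m is None:
        m = MembraneParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    G, relax = membrane_constants(m)
    out = (sigma0 / G) * (1.0 - np.exp(-t / relax))
    return float(out) if out.ndim == 0 else out


def contour_profile(shape: ShapeParams | None = None, n_samples: int = 512) -> np.ndarray:
    """Sampled closed x-z contour, shape (2*n_samples - 1, 2), for plotting."""
    if shape is None:
        shape = ShapeParams()
    x = np.linspace(-shape.D0 / 2.0, shape.D0 / 2.0, n_samples)
    z = biconcave_z(x, 0.0, shape)
    xs = np.concatenate([x, x[::-1][1:]])
    zs = np.concatenate([z, -z[::-1][1:]])
    return np.column_stack([xs, zs])
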