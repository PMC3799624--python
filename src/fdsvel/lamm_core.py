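"""Finite-volume Lamm-equation solver for sector-shaped ultracentrifuge cells.

The Lamm equation describes the evolution of the concentration profile
chi(r, t) of an ideally sedimenting, diffusing species in a sector-shaped
solution column rotating at angular velocity omega::

    d(chi)/dt = (1/r) d/dr [ r D d(chi)/dr - s omega^2 r^2 chi ]

with zero-flux (reflecting) boundaries at the meniscus ``m`` (air/solution
interface, lowest radius) and the bottom ``b`` (highest radius).  The solver
discretizes the conservation form on a fixed radial grid with
Scharfetter-Gummel (exponentially fitted) face fluxes, which remain stable
and mass-conserving from the diffusion-dominated to the pure-advection
limit, and advances in time with Crank-Nicolson steps.

Finite rotor acceleration is handled through the effective-time
transformation: the constant-speed solution is evaluated at the equivalent
time ``int omega(t')^2 dt' / omega^2``, the standard first-order treatment
for a linear speed ramp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

#: 1 Svedberg in seconds.
SVEDBERG = 1e-13
#: Boltzmann constant, erg/K.
KB = 1.380649e-16
#: Gas constant, erg/(mol K).
R_GAS = 8.314462618e7


@dataclass
class CellModel:
    """Geometry and rotor-speed profile of one solution column.

    Parameters
    ----------
    meniscus : float
        Radius of the air/solution interface, cm from the rotor center.
    bottom : float
        Radius of the cell bottom (highest radius of the column), cm.
    rpm : float
        Final rotor speed, revolutions per minute.
    t_acc : float
        Duration of the linear acceleration ramp from rest to ``rpm``,
        seconds.  Zero means instantaneous start.
    sector : bool
        Sector-shaped column (the only supported geometry; kept as an
        explicit flag for clarity).
    """

    meniscus: float
    bottom: float
    rpm: float
    t_acc: float = 0.0
    sector: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.meniscus < self.bottom:
            raise ValueError(
                f"require 0 < meniscus < bottom, got m={self.meniscus}, b={self.bottom}"
            )
        if self.rpm <= 0:
            raise ValueError("rpm must be positive")
        if self.t_acc < 0:
            raise ValueError("acceleration time must be >= 0")

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return self.rpm * np.pi / 30.0


@dataclass
class SpeciesParams:
    """One ideally sedimenting species.

    ``s`` is entered in Svedberg (1e-13 s) as customary; ``D`` in cm^2/s;
    ``c0`` is the uniform loading signal in detector counts, referenced to
    the meniscus at the start of centrifugation.
    """

    s: float
    D: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.c0 < 0:
            raise ValueError("loading signal must be >= 0")


@dataclass
class SolutionConditions:
    """Solvent density/viscosity and solute partial-specific volume.

    Defaults are water at 20 C with a typical protein vbar, chosen so that
    s-values pass through essentially uncorrected (experimental s-values in
    this workflow are customarily reported without buffer correction).
    """

    density: float = 0.99823  # g/ml
    viscosity: float = 0.010016  # poise
    vbar: float = 0.73  # ml/g
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "vbar", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vbar * self.density >= 1.0:
            warnings.warn(
                "vbar * density >= 1: species is neutrally or negatively buoyant",
                stacklevel=2,
            )

    @property
    def buoyancy(self) -> float:
        """Buoyancy factor (1 - vbar * rho)."""
        return 1.0 - self.vbar * self.density


def effective_time(times, cell: CellModel):
    """Integral of omega(t')^2 from 0 to t under a linear rotor-speed ramp.

    For a ramp completing at ``t_acc`` the integral is
    ``omega^2 t^3 / (3 t_acc^2)`` during acceleration and
    ``omega^2 (t - 2 t_acc / 3)`` afterwards; with ``t_acc = 0`` it is
    exactly ``omega^2 t``.  Returned in rad^2/s.
    """
    t = np.asarray(times, dtype=float)
    w2 = cell.omega**2
    if cell.t_acc == 0.0:
        out = w2 * t
    else:
        ta = cell.t_acc
        out = np.where(t < ta, w2 * t**3 / (3.0 * ta**2), w2 * (t - 2.0 * ta / 3.0))
    return out if np.ndim(times) else float(out)


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), computed stably for all x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    big = x > 500.0
    neg = x < -500.0
    mid = ~(small | big | neg)
    out[small] = 1.0 - 0.5 * x[small]
    out[big] = 0.0
    out[neg] = -x[neg]
    out[mid] = x[mid] / np.expm1(x[mid])
    return out


def _assemble_operator(species: SpeciesParams, cell: CellModel, n_grid: int):
    """Tridiagonal transport operator A with d(chi)/dt = A chi.

    Returns (r, lower, main, upper) with lower/upper of length n-1.
    Face fluxes use the Scharfetter-Gummel discretization; the operator
    conserves the sector mass  sum_i V_i chi_i  exactly.
    """
    m, b = cell.meniscus, cell.bottom
    r = np.linspace(m, b, n_grid)
    dr = r[1] - r[0]
    rf = 0.5 * (r[:-1] + r[1:])
    h = np.full(n_grid, dr)
    h[0] = h[-1] = 0.5 * dr
    vol = r * h

    sv = species.s * SVEDBERG
    vf = sv * cell.omega**2 * rf  # advection velocity at faces, cm/s
    if species.D > 0:
        pe = vf * dr / species.D
        coef = species.D / dr * rf
        a = coef * _bernoulli(-pe)  # multiplies chi at the left node
        c = coef * _bernoulli(pe)  # multiplies chi at the right node
    else:
        # pure advection: upwind
        a = rf * np.maximum(vf, 0.0)
        c = rf * np.maximum(-vf, 0.0)

    n = n_grid
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    # face j sits between nodes j and j+1; flux F_j = a_j chi_j - c_j chi_{j+1}
    main[:-1] -= a / vol[:-1]
    upper[:] = c / vol[:-1]
    lower[:] = a / vol[1:]
    main[1:] -= c / vol[1:]
    return r, vol, lower, main, upper


def solve_lamm(
    species: SpeciesParams,
    cell: CellModel,
    times,
    radii,
    *,
    n_grid: int = 1000,
    courant: float = 0.5,
    clamp: bool = False,
) -> np.ndarray:
    """Solve the Lamm equation, returning chi at the requested radii and times.

    Parameters
    ----------
    species, cell
        Species and cell descriptions.
    times : array-like
        Ascending elapsed times since start of centrifugation, s.
    radii : array-like
        Observation radii, cm, normally within [meniscus, bottom].
    n_grid : int
        Internal radial grid size (uniform).
    courant : float
        Advective Courant number limiting the internal time step.
    clamp : bool
        If True, radii outside the solution column are assigned the value
        at the nearest column end instead of raising.  Used by the fitter
        when the bottom position floats below the last data point.

    Returns
    -------
    ndarray, shape (n_times, n_radii)
        chi(r, t) in the units of ``species.c0``.  The profile at t = 0 is
        the uniform loading concentration; boundaries are reflecting, so
        total sector mass is conserved.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    m, b = cell.meniscus, cell.bottom
    tol_r = 1e-9
    if not clamp and (radii.min() < m - tol_r or radii.max() > b + tol_r):
        raise ValueError(
            f"radii must lie within the solution column [{m}, {b}] "
            "(pass clamp=True to clip)"
        )

    r, _vol, lower, main, upper = _assemble_operator(species, cell, n_grid)
    dr = r[1] - r[0]
    w2 = cell.omega**2
    tau = np.asarray(effective_time(times, cell), dtype=float) / w2

    chi = np.full(n_grid, float(species.c0))
    out = np.empty((times.size, radii.size))

    v_max = abs(species.s) * SVEDBERG * w2 * b
    dt_max = courant * dr / v_max if v_max > 0 else np.inf

    theta = 0.5  # Crank-Nicolson
    tau_prev = 0.0
    for k, tk in enumerate(tau):
        span = tk - tau_prev
        if span > 0 and (v_max > 0 or species.D > 0):
            nsub = max(1, int(np.ceil(span / dt_max))) if np.isfinite(dt_max) else 1
            dt = span / nsub
            ab = np.zeros((3, n_grid))
            ab[0, 1:] = -theta * dt * upper
            ab[1, :] = 1.0 - theta * dt * main
            ab[2, :-1] = -theta * dt * lower
            for _ in range(nsub):
                rhs = chi + (1.0 - theta) * dt * (
                    main * chi
                    + np.concatenate(([0.0], lower * chi[:-1]))
                    + np.concatenate((upper * chi[1:], [0.0]))
                )
                chi = solve_banded((1, 1), ab, rhs)
        out[k] = np.interp(radii, r, chi)
        tau_prev = tk
    return out


def sector_mass(chi_row, radii) -> float:
    """Sector mass integral  int chi(r) r dr  by trapezoidal quadrature."""
    radii = np.asarray(radii, dtype=float)
    return float(np.trapezoid(np.asarray(chi_row) * radii, radii))
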