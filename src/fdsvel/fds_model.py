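"""Signal transforms specific to the confocal fluorescence detector (FDS).

The fluorescence optics superimpose four instrument signatures on the ideal
sedimentation signal chi(r, t):

* a radial magnification gradient and a temporal intensity drift, modeled
  to first order as a multiplicative factor
  ``1 + (de/dr)0 (r - m) + (de/dt)0 t`` normalized to unity at the meniscus
  at t = 0, so fitted concentrations stay in signal units at the meniscus;
* a shadow cast by the centerpiece at the cell bottom, modeled as the
  obscured area fraction of a uniform circular beam cross-section of radius
  ``delta`` intersected by the wall at radius ``b``;
* a radial convolution by a Gaussian of width ``sigma`` (FWHM = 1.67 sigma
  under the kernel convention exp(-(dr/sigma)^2)), truncated at
  ``trunc_n * sigma``;
* an optional power-law signal non-linearity ``a_obs = a0 + c**kappa``
  (inner-filter effects), handled by back-transforming the data into
  concentration-linear units before the distribution analysis.

All three radial/temporal transforms are linear operators on chi and are
applied per basis function; the convolution is applied after the
magnification and shadow transforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

logger = logging.getLogger(__name__)

_SECONDS_PER_HOUR = 3600.0


@dataclass
class FdsParams:
    """The four detector parameters of the FDS signal model.

    Parameters
    ----------
    de_dr : float
        Radial magnification gradient (de/dr)0, 1/cm.
    de_dt : float
        Temporal intensity drift (de/dt)0, entered per hour (the customary
        reporting unit); converted to 1/s internally.
    delta : float
        Beam half-width (cross-section radius) of the detection/excitation
        cone at the bottom, cm.
    sigma : float
        Radial Gaussian convolution width, cm.
    trunc_n : int
        Kernel truncation in multiples of sigma (default 3).
    drift_mode : str
        "linear" for the first-order drift term, "exponential" for an
        exponential intensity decay with rate ``de_dt`` (useful for
        strongly bleaching fluorophores).
    """

    de_dr: float = 0.0
    de_dt: float = 0.0
    delta: float = 0.0
    sigma: float = 0.0
    trunc_n: int = 3
    drift_mode: str = "linear"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.trunc_n < 1:
            raise ValueError("trunc_n must be >= 1")
        if self.drift_mode not in ("linear", "exponential"):
            raise ValueError("drift_mode must be 'linear' or 'exponential'")

    @property
    def de_dt_per_s(self) -> float:
        """Temporal drift in 1/s."""
        return self.de_dt / _SECONDS_PER_HOUR


@dataclass
class NonlinearityParams:
    """Power-law signal response  a_obs = a0 + c**kappa.

    ``a0`` is a baseline offset in counts restricting the power law to the
    macromolecular signal; ``kappa`` is the dimensionless power coefficient
    (unity for a perfectly linear detector).
    """

    a0: float = 0.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def temporal_drift_factor(t, fds: FdsParams):
    """Dimensionless intensity factor of the temporal drift at time t (s).

    Linear mode returns ``1 + (de/dt)0 t``; exponential mode returns
    ``exp((de/dt)0 t)``.  Both equal 1 at t = 0 and agree to first order.
    """
    t = np.asarray(t, dtype=float)
    k = fds.de_dt_per_s
    if fds.drift_mode == "exponential":
        out = np.exp(k * t)
    else:
        out = 1.0 + k * t
    return out if out.ndim else float(out)


def apply_rt(chi, m, de_dr, de_dt, radii, times, drift_mode: str = "linear"):
    """Radial-magnification / temporal-drift transform T_rt.

    Multiplies chi(r, t) by the first-order magnification profile
    ``eps(r, t) = 1 + de_dr (r - m) + drift(t)`` with eps(m, 0) = 1, where
    the drift term is ``de_dt * t`` (linear) or ``exp(de_dt t) - 1``
    (exponential).  ``de_dt`` here is in 1/s.

    Parameters are in the same normalization as the fit: concentration
    amplitudes resulting from an analysis with this transform are in signal
    units at the meniscus at the start of centrifugation.
    """
    chi = np.asarray(chi, dtype=float)
    radii = np.asarray(radii, dtype=float)
    times = np.asarray(times, dtype=float)
    if chi.shape != (times.size, radii.size):
        raise ValueError("chi must have shape (n_times, n_radii)")
    if drift_mode == "exponential":
        drift = np.expm1(de_dt * times)
    else:
        drift = de_dt * times
    eps = 1.0 + de_dr * (radii - m)[None, :] + drift[:, None]
    if np.any(eps <= 0):
        warnings.warn(
            "magnification factor <= 0 within the fit range "
            "(drift/gradient parameters are running away)",
            stacklevel=2,
        )
    return eps * chi


def shadow_fraction(r, b, delta):
    """Obscured area fraction B(r, b, delta) of the beam at the cell bottom.

    A uniform circular beam cross-section of radius ``delta`` centered at
    radius ``r`` is cut by the wall at ``b``; B is the fractional area of
    the circular segment beyond the wall.  With h = b - r and |h| <= delta::

        B = [delta^2 arccos(h/delta) - h sqrt(delta^2 - h^2)] / (pi delta^2)

    B is 0 for r <= b - delta (beam fully inside the column), rises smoothly
    to exactly 1/2 at r = b, and continues symmetrically to 1 at
    r >= b + delta.  ``delta = 0`` degenerates to a step at b.
    """
    r_arr = np.asarray(r, dtype=float)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0.0:
        out = np.where(r_arr < b, 0.0, np.where(r_arr > b, 1.0, 0.5))
    else:
        h = np.clip(b - r_arr, -delta, delta)
        out = (delta**2 * np.arccos(h / delta) - h * np.sqrt(delta**2 - h**2)) / (
            np.pi * delta**2
        )
        # snap to the exact limits within one part in 1e12 of the beam edge,
        # where the arccos evaluation loses all significant digits anyway
        out = np.where(delta - h <= 1e-12 * delta, 0.0, out)
        out = np.where(delta + h <= 1e-12 * delta, 1.0, out)
    return out if out.ndim else float(out)


def apply_shadow(signal, b, delta, radii):
    """Bottom-shadow transform T_S: multiply by (1 - B(r, b, delta)).

    ``delta = 0`` means no shadow is modeled and the transform is the
    identity (the degenerate step of :func:`shadow_fraction` is not
    applied to data).
    """
    signal = np.asarray(signal, dtype=float)
    if delta == 0.0:
        return signal.copy()
    radii = np.asarray(radii, dtype=float)
    return signal * (1.0 - shadow_fraction(radii, b, delta))[None, :]


def _gaussian_kernel(sigma: float, dr: float, trunc_n: int) -> np.ndarray | None:
    """Discrete kernel exp(-(dr_k/sigma)^2) on |dr_k| <= trunc_n sigma.

    Returns None when the kernel degenerates to a single point (sigma below
    half the radial spacing), meaning the convolution is the identity.
    """
    if sigma < 0.5 * dr:
        return None
    half = int(np.floor(trunc_n * sigma / dr))
    if half < 1:
        return None
    offs = np.arange(-half, half + 1) * dr
    k = np.exp(-((offs / sigma) ** 2))
    return k / k.sum()


def gaussian_convolve(signal, sigma, trunc_n, radii):
    """Radial convolution transform T_C with a truncated Gaussian kernel.

    The kernel convention is ``exp(-(dr/sigma)^2)`` so its FWHM is
    ``2 sigma sqrt(ln 2) ~= 1.67 sigma``.  The kernel is renormalized to
    unit sum, and near the data edges the effective local weights are
    renormalized as well, so constant fields are preserved exactly
    everywhere.  Requires uniformly spaced radii (tolerance 1e-6 cm).
    """
    signal = np.asarray(signal, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if radii.size < 2 or sigma == 0.0:
        return signal.copy()
    spacings = np.diff(radii)
    dr = float(np.median(spacings))
    if np.any(np.abs(spacings - dr) > 1e-6):
        raise ValueError(
            "gaussian_convolve requires uniformly spaced radii "
            "(resample the scan to a uniform grid first)"
        )
    k = _gaussian_kernel(sigma, dr, trunc_n)
    if k is None:
        return signal.copy()
    num = convolve1d(signal, k, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(np.ones(radii.size), k, mode="constant", cval=0.0)
    return num / den[None, :] if signal.ndim == 2 else num / den


def compose_fds(chi, cell, fds: FdsParams, radii, times):
    """Full detector model: T_C applied after T_rt and T_S.

    Linear in chi, so it can be imposed on each Lamm-equation solution of a
    mixture or distribution before the linear distribution analysis.
    """
    out = apply_rt(
        chi,
        cell.meniscus,
        fds.de_dr,
        fds.de_dt_per_s,
        radii,
        times,
        drift_mode=fds.drift_mode,
    )
    out = apply_shadow(out, cell.bottom, fds.delta, radii)
    return gaussian_convolve(out, fds.sigma, fds.trunc_n, radii)


def linearize_signal(a_obs, nl: NonlinearityParams):
    """Back-transform observed counts into concentration-linear units.

    Inverts ``a_obs = a0 + c**kappa`` as ``c = (a_obs - a0)**(1/kappa)``.
    With kappa = 1 this is a pure baseline subtraction and is exact for
    negative excursions as well; for kappa != 1 values below a0 are clamped
    to zero (their count is logged).
    """
    a = np.asarray(a_obs, dtype=float)
    if nl.kappa == 1.0:
        out = a - nl.a0
    else:
        shifted = a - nl.a0
        n_clamped = int(np.count_nonzero(shifted < 0))
        if n_clamped:
            logger.info("linearize_signal: clamped %d values below a0", n_clamped)
        out = np.clip(shifted, 0.0, None) ** (1.0 / nl.kappa)
    return out if out.ndim else float(out)


def delinearize_signal(c, nl: NonlinearityParams):
    """Forward power law: map concentration-linear units back to counts.

    ``a_obs = a0 + c**kappa``; used to return a fitted model to the data
    space for residual inspection.  With kappa = 1 this is an exact offset.
    Slightly negative inputs (solver tolerance) are clamped at zero when
    kappa != 1.
    """
    c_arr = np.asarray(c, dtype=float)
    if nl.kappa == 1.0:
        out = c_arr + nl.a0
    else:
        out = nl.a0 + np.clip(c_arr, 0.0, None) ** nl.kappa
    return out if out.ndim else float(out)
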