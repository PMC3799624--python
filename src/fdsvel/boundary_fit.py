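"""c(s) direct boundary fitting of FDS sedimentation velocity data.

The sedimentation-coefficient distribution c(s) models the data as a
regularized non-negative linear combination of Lamm-equation solutions
sharing one frictional ratio f/f0, each passed through the detector
transforms (magnification gradient, drift, bottom shadow, radial
convolution) before the linear analysis.  Systematic time-invariant (TI,
per-radius) and radial-invariant (RI, per-scan) offsets are eliminated
algebraically by projecting data and basis onto the orthogonal complement
of the offset subspaces, so fitted amplitudes and the rmsd are exactly
invariant under the addition of arbitrary TI/RI contributions.

The outer, non-linear refinement over geometry (meniscus, bottom),
frictional ratio and the four detector parameters wraps the linear
subproblem in a derivative-free simplex search with box constraints
implemented through a sin^2 parameter transformation, following the
statsmodels convention of a model object whose ``fit()`` returns a results
object (:class:`CsFit` / :class:`CsFitResults`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .fds_model import (
    FdsParams,
    NonlinearityParams,
    compose_fds,
    delinearize_signal,
    linearize_signal,
)
from .lamm_core import (
    KB,
    R_GAS,
    SVEDBERG,
    CellModel,
    SolutionConditions,
    SpeciesParams,
    solve_lamm,
)
from .scan_io import ScanSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hydrodynamic conversions


def diffusion_from_ff0(s: float, ff0: float, cond: SolutionConditions) -> float:
    """Diffusion coefficient implied by s and the frictional ratio.

    Uses the c(s) scaling law

        D(s) = (sqrt(2)/18 pi) kT s^(-1/2) (eta f/f0)^(-3/2)
               ((1 - vbar rho)/vbar)^(1/2)

    with ``s`` in seconds (not Svedberg), returning D in cm^2/s.
    """
    if s <= 0:
        raise ValueError("s must be positive (in seconds)")
    if ff0 < 1.0:
        raise ValueError("frictional ratio must be >= 1")
    buoy = cond.buoyancy
    if buoy <= 0:
        raise ValueError("vbar * density >= 1: no positive buoyancy")
    kT = KB * cond.temperature
    return (
        (np.sqrt(2.0) / (18.0 * np.pi))
        * kT
        * s ** (-0.5)
        * (cond.viscosity * ff0) ** (-1.5)
        * (buoy / cond.vbar) ** 0.5
    )


def svedberg_mass(s: float, D: float, cond: SolutionConditions) -> float:
    """Molar mass from the Svedberg equation, M = sRT / (D (1 - vbar rho)).

    ``s`` in seconds, ``D`` in cm^2/s; returns kDa.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    buoy = cond.buoyancy
    if buoy <= 0:
        raise ValueError("vbar * density >= 1: no positive buoyancy")
    return s * R_GAS * cond.temperature / (D * buoy) / 1000.0


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CsModel:
    """A fitted sedimentation-coefficient distribution.

    ``amplitudes`` are the distribution density c(s) at the grid nodes, in
    signal units (at the meniscus at the start of centrifugation) per
    Svedberg; ``ti``/``ri`` are the algebraic systematic-noise vectors.
    """

    s_grid: np.ndarray
    ff0: float
    amplitudes: np.ndarray
    reg_alpha: float = 0.0
    ti: np.ndarray | None = None
    ri: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if self.amplitudes.shape != self.s_grid.shape:
            raise ValueError("amplitudes must match s_grid")
        if np.any(self.amplitudes < -1e-12):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class FitReport:
    """Best-fit parameters and derived quantities of one boundary fit."""

    fds: FdsParams
    cell_model: CellModel
    ff0: float
    rmsd: float
    s_w: float
    boundary_amplitude: float
    mw_app_kda: float
    cs: CsModel | None = None
    residuals: np.ndarray | None = None
    run_id: str = ""
    cell: int = 1
    gain: int = 1
    focal_depth_um: float | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# linear subproblem


def _center(X: np.ndarray, fit_ti: bool, fit_ri: bool) -> np.ndarray:
    """Project (n_scans, n_radii) fields onto the complement of TI/RI space."""
    if fit_ti:
        X = X - X.mean(axis=-2, keepdims=True)
    if fit_ri:
        X = X - X.mean(axis=-1, keepdims=True)
    return X


def _second_difference(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    L = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    L[idx, idx] = 1.0
    L[idx, idx + 1] = -2.0
    L[idx, idx + 2] = 1.0
    return L


@dataclass
class SubproblemResult:
    amplitudes: np.ndarray
    ti: np.ndarray
    ri: np.ndarray
    rmsd: float
    model: np.ndarray  # basis * amplitudes, without TI/RI


def solve_linear_subproblem(
    data,
    basis: np.ndarray,
    reg_alpha: float = 0.0,
    fit_ti: bool = True,
    fit_ri: bool = False,
) -> SubproblemResult:
    """Non-negative least squares with algebraic TI/RI noise decomposition.

    Parameters
    ----------
    data : ScanSet or ndarray (n_scans, n_radii)
        Observed signals.
    basis : ndarray (n_basis, n_scans, n_radii)
        Detector-transformed Lamm solutions, already scaled by the s-grid
        quadrature weights so the amplitudes are distribution densities.
    reg_alpha : float
        Tikhonov second-difference penalty weight.
    fit_ti, fit_ri : bool
        Whether per-radius (TI) and per-scan (RI) offsets are modeled.

    Minimizes ``||data - basis.c - TI - RI||^2 + alpha ||L c||^2`` over
    ``c >= 0`` with the offsets eliminated by projection; TI/RI are
    recovered from the residual field afterwards (the shared-constant
    degeneracy is resolved by giving RI zero mean).
    """
    Y = data.signal_matrix() if isinstance(data, ScanSet) else np.asarray(data, float)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 3 or basis.shape[1:] != Y.shape:
        raise ValueError("basis must have shape (n_basis, n_scans, n_radii)")
    n_basis = basis.shape[0]
    Yc = _center(Y, fit_ti, fit_ri)
    Bc = _center(basis, fit_ti, fit_ri)

    A = Bc.reshape(n_basis, -1).T
    y = Yc.ravel()
    if reg_alpha > 0:
        L = _second_difference(n_basis)
        A = np.vstack([A, np.sqrt(reg_alpha) * L])
        y = np.concatenate([y, np.zeros(L.shape[0])])

    try:
        c, _ = optimize.nnls(A, y, maxiter=max(50 * n_basis, 1000))
    except RuntimeError:
        # severe rank deficiency after projection: apply a regularization floor
        logger.warning("NNLS failed to converge; applying a regularization floor")
        scale = np.mean(A**2) * A.shape[0]
        L = _second_difference(n_basis)
        A2 = np.vstack([A, np.sqrt(1e-8 * scale) * L])
        y2 = np.concatenate([y, np.zeros(L.shape[0])])
        c, _ = optimize.nnls(A2, y2, maxiter=max(100 * n_basis, 2000))

    model = np.tensordot(c, basis, axes=1)
    R = Y - model
    ti = R.mean(axis=0) if fit_ti else np.zeros(Y.shape[1])
    R2 = R - ti[None, :]
    ri = R2.mean(axis=1) if fit_ri else np.zeros(Y.shape[0])
    resid = R2 - ri[:, None]
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return SubproblemResult(amplitudes=c, ti=ti, ri=ri, rmsd=rmsd, model=model)


def select_regularization(
    data,
    basis: np.ndarray,
    fit_ti: bool = True,
    fit_ri: bool = False,
    p_level: float = 0.683,
    max_iter: int = 40,
) -> float:
    """Pick the Tikhonov weight by the one-sigma F-ratio criterion.

    Increases alpha until the regularized chi-square exceeds the best-fit
    chi-square by the F-statistic ratio at confidence ``p_level`` (the
    convention of the c(s) method), then refines by log-bisection.
    Returns alpha (possibly 0 when even strong smoothing is statistically
    free, e.g. for a noise-free single species).
    """
    Y = data.signal_matrix() if isinstance(data, ScanSet) else np.asarray(data, float)
    base = solve_linear_subproblem(Y, basis, 0.0, fit_ti, fit_ri)
    chi0 = base.rmsd**2
    if chi0 <= 0:
        return 0.0
    n = Y.size
    dof = max(n - basis.shape[0], 1)
    target = chi0 * stats.f.ppf(p_level, dof, dof)

    # bracket: expand alpha until chi2(alpha) crosses the target
    scale = float(np.mean(basis**2)) * n
    lo, hi = 0.0, 1e-9 * scale
    chi_hi = solve_linear_subproblem(Y, basis, hi, fit_ti, fit_ri).rmsd ** 2
    it = 0
    while chi_hi < target and it < max_iter:
        lo, hi = hi, hi * 10.0
        chi_hi = solve_linear_subproblem(Y, basis, hi, fit_ti, fit_ri).rmsd ** 2
        it += 1
    if chi_hi < target:
        return hi  # smoothing saturates below the confidence level
    for _ in range(25):
        mid = np.sqrt(max(lo, 1e-12 * hi) * hi)
        chi_mid = solve_linear_subproblem(Y, basis, mid, fit_ti, fit_ri).rmsd ** 2
        if chi_mid < target:
            lo = mid
        else:
            hi = mid
        if hi / max(lo, 1e-300) < 1.05:
            break
    return lo


# ---------------------------------------------------------------------------
# distribution integration and fit range


def integrate_cs(model: CsModel, s_lo: float | None = None, s_hi: float | None = None):
    """Integrate c(s): returns (s_w, amplitude) over [s_lo, s_hi].

    ``amplitude`` is the trapezoidal integral of the distribution (the
    boundary signal referenced to the meniscus at the start of
    centrifugation) and ``s_w`` the signal-weighted average s.  A zero
    integral yields amplitude 0 and s_w = nan with a warning.
    """
    s = model.s_grid
    c = model.amplitudes
    if s_lo is None:
        s_lo = s[0]
    if s_hi is None:
        s_hi = s[-1]
    if not s_lo < s_hi:
        raise ValueError("require s_lo < s_hi")
    mask = (s >= s_lo) & (s <= s_hi)
    if mask.sum() < 2:
        raise ValueError("integration range must cover at least two grid points")
    ss, cc = s[mask], c[mask]
    amplitude = float(np.trapezoid(cc, ss))
    if amplitude <= 0:
        warnings.warn("zero distribution integral: s_w undefined", stacklevel=2)
        return float("nan"), 0.0
    # exact first moment of the piecewise-linear density
    h = np.diff(ss)
    c0, c1 = cc[:-1], cc[1:]
    s0, s1 = ss[:-1], ss[1:]
    moment = float(np.sum(h * ((2.0 * c0 + c1) * s0 + (c0 + 2.0 * c1) * s1) / 6.0))
    return moment / amplitude, amplitude


def default_fit_range(cell: CellModel, delta: float) -> tuple[float, float]:
    """Default radial fit window (r_min, r_max) = (m + 2 delta, b).

    Data closer to the meniscus than the detection-cone diameter (as
    measured from the bottom shadow) are excluded; the bottom region is
    retained because the shadow transform models it.
    """
    r_min = cell.meniscus + 2.0 * delta
    r_max = cell.bottom
    if r_min >= r_max:
        raise ValueError("fit range is empty: meniscus + 2 delta >= bottom")
    return r_min, r_max


# ---------------------------------------------------------------------------
# outer model


_PARAM_NAMES = ("meniscus", "bottom", "ff0", "de_dr", "de_dt", "delta", "sigma")


def _default_bounds(cell: CellModel) -> dict[str, tuple[float, float]]:
    return {
        "meniscus": (cell.meniscus - 0.05, cell.meniscus + 0.05),
        "bottom": (cell.bottom - 0.05, cell.bottom + 0.05),
        "ff0": (1.0, 4.0),
        "de_dr": (-2.0, 2.0),
        "de_dt": (-0.2, 0.2),  # per hour
        "delta": (0.0, 0.5),
        "sigma": (0.0, 0.1),
    }


class _BoxTransform:
    """Map unconstrained simplex coordinates to box-bounded parameters.

    p = lo + (hi - lo) sin^2(x); initial values at a bound are nudged 2%
    into the interior so the transform has a usable local derivative.
    """

    def __init__(self, bounds: list[tuple[float, float]]):
        self.bounds = bounds

    def to_x(self, p: np.ndarray) -> np.ndarray:
        x = np.empty(len(p))
        for i, (v, (lo, hi)) in enumerate(zip(p, self.bounds)):
            span = hi - lo
            frac = np.clip((v - lo) / span, 0.02, 0.98)
            x[i] = np.arcsin(np.sqrt(frac))
        return x

    def to_p(self, x: np.ndarray) -> np.ndarray:
        p = np.empty(len(x))
        for i, (xi, (lo, hi)) in enumerate(zip(x, self.bounds)):
            p[i] = lo + (hi - lo) * np.sin(xi) ** 2
        return p


class _LammCache:
    """Memoize Lamm solutions keyed by (s, D, geometry)."""

    def __init__(self):
        self._store: dict = {}

    def get(self, s, D, cell: CellModel, times_key, radii, n_grid, courant):
        key = (
            round(float(s), 9),
            round(float(D), 16),
            round(cell.meniscus, 7),
            round(cell.bottom, 7),
            round(cell.rpm, 3),
            round(cell.t_acc, 3),
            times_key,
            n_grid,
        )
        chi = self._store.get(key)
        if chi is None:
            chi = solve_lamm(
                SpeciesParams(s=float(s), D=float(D), c0=1.0),
                cell,
                times_key[1],
                radii,
                n_grid=n_grid,
                courant=courant,
                clamp=True,
            )
            self._store[key] = chi
        return chi


class CsFit:
    """Direct boundary c(s) model of one FDS-SV data set.

    Statsmodels-style model object: construct from a :class:`ScanSet` (or a
    raw signal matrix plus grids), configure which parameters float, and
    call :meth:`fit` to obtain a :class:`CsFitResults`.

    Parameters
    ----------
    data : ScanSet or ndarray (n_scans, n_radii)
        Observed fluorescence scans.
    cell : CellModel
        Initial column geometry and rotor profile.
    radii, times : arrays, required when ``data`` is a bare matrix.
    conditions : SolutionConditions
        Buffer/solute parameters for s <-> D <-> M conversions.
    s_grid : array, default 100 linear points over 0.1-10 S.
    ff0 : float
        Initial frictional ratio.
    fds : FdsParams
        Initial detector parameters (also the fixed values for any
        parameter not floated).
    nonlinearity : NonlinearityParams or None
        When given, data are back-transformed into concentration-linear
        units before fitting and the reported rmsd/residuals are in the
        raw data space.
    float_params : sequence of names among
        {meniscus, bottom, ff0, de_dr, de_dt, delta, sigma}.
    fit_range : (r_min, r_max) or None for the default meniscus-exclusion
        rule based on the initial delta.
    reg_alpha : float or "auto"
        Tikhonov weight for the final distribution; "auto" selects it by
        the one-sigma F-ratio criterion.  The outer parameter refinement
        itself runs unregularized.
    """

    def __init__(
        self,
        data,
        cell: CellModel,
        *,
        radii=None,
        times=None,
        conditions: SolutionConditions | None = None,
        s_grid=None,
        ff0: float = 1.3,
        fds: FdsParams | None = None,
        nonlinearity: NonlinearityParams | None = None,
        float_params=("ff0",),
        bounds: dict | None = None,
        fit_range=None,
        fit_ti: bool = True,
        fit_ri: bool = False,
        reg_alpha="auto",
        n_grid: int = 600,
        courant: float = 0.5,
    ):
        if isinstance(data, ScanSet):
            self.radii_all = data.radii
            self.times = data.times
            self.Y_raw = data.signal_matrix()
            self.scanset = data
        else:
            if radii is None or times is None:
                raise ValueError("radii and times are required with a bare matrix")
            self.radii_all = np.asarray(radii, dtype=float)
            self.times = np.asarray(times, dtype=float)
            self.Y_raw = np.asarray(data, dtype=float)
            self.scanset = None
        self.cell0 = cell
        self.conditions = conditions or SolutionConditions()
        self.s_grid = (
            np.linspace(0.1, 10.0, 100) if s_grid is None else np.asarray(s_grid, float)
        )
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        self.ff0_init = ff0
        self.fds_init = fds or FdsParams()
        self.nonlinearity = nonlinearity
        self.float_params = tuple(float_params)
        unknown = set(self.float_params) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown float parameters: {sorted(unknown)}")
        self.bounds = _default_bounds(cell)
        if bounds:
            self.bounds.update(bounds)
        self.fit_ti = fit_ti
        self.fit_ri = fit_ri
        self.reg_alpha = reg_alpha
        self.n_grid = n_grid
        self.courant = courant
        self._cache = _LammCache()

        if fit_range is None:
            fit_range = default_fit_range(cell, self.fds_init.delta)
        self.fit_range = fit_range
        mask = (self.radii_all >= fit_range[0] - 1e-12) & (
            self.radii_all <= fit_range[1] + 1e-12
        )
        if mask.sum() < 5:
            raise ValueError("fewer than 5 radii inside the fit range")
        self._mask = mask
        self.radii = self.radii_all[mask]
        self.Y = self.Y_raw[:, mask]
        if self.nonlinearity is not None:
            self.Y_fitspace = linearize_signal(self.Y, self.nonlinearity)
        else:
            self.Y_fitspace = self.Y

        if len(self.times) < 10 and "de_dt" in self.float_params:
            warnings.warn(
                "fewer than 10 scans: the temporal drift is weakly identified "
                "against radial dilution",
                stacklevel=2,
            )
        # quadrature weights making amplitudes a density over s
        s = self.s_grid
        w = np.empty_like(s)
        w[0] = 0.5 * (s[1] - s[0])
        w[-1] = 0.5 * (s[-1] - s[-2])
        if s.size > 2:
            w[1:-1] = 0.5 * (s[2:] - s[:-2])
        self._s_weights = w
        self._times_key = (hash(self.times.tobytes()), tuple(self.times))

    # -- pieces ------------------------------------------------------------

    def _params_from_vector(self, names, values) -> tuple[CellModel, float, FdsParams]:
        d = dict(zip(names, values))
        cell = replace(
            self.cell0,
            meniscus=d.get("meniscus", self.cell0.meniscus),
            bottom=d.get("bottom", self.cell0.bottom),
        )
        ff0 = d.get("ff0", self.ff0_init)
        fds = replace(
            self.fds_init,
            de_dr=d.get("de_dr", self.fds_init.de_dr),
            de_dt=d.get("de_dt", self.fds_init.de_dt),
            delta=d.get("delta", self.fds_init.delta),
            sigma=d.get("sigma", self.fds_init.sigma),
        )
        return cell, ff0, fds

    def build_basis(self, cell: CellModel, ff0: float, fds: FdsParams) -> np.ndarray:
        """Quadrature-weighted, detector-transformed Lamm basis functions."""
        n_s = self.s_grid.size
        basis = np.empty((n_s, self.times.size, self.radii.size))
        for k, s in enumerate(self.s_grid):
            D = diffusion_from_ff0(s * SVEDBERG, ff0, self.conditions)
            chi = self._cache.get(
                s, D, cell, self._times_key, self.radii, self.n_grid, self.courant
            )
            basis[k] = compose_fds(chi, cell, fds, self.radii, self.times)
        return basis * self._s_weights[:, None, None]

    def objective(self, names, values) -> float:
        """rmsd (in the fitting space) for one outer-parameter vector."""
        cell, ff0, fds = self._params_from_vector(names, values)
        basis = self.build_basis(cell, ff0, fds)
        sub = solve_linear_subproblem(
            self.Y_fitspace, basis, 0.0, self.fit_ti, self.fit_ri
        )
        return sub.rmsd

    # -- fitting -----------------------------------------------------------

    def fit(self, maxiter: int = 600, xatol: float = 3e-4, fatol_rel: float = 1e-7):
        """Run the outer refinement and return a :class:`CsFitResults`."""
        names = list(self.float_params)
        init_map = {
            "meniscus": self.cell0.meniscus,
            "bottom": self.cell0.bottom,
            "ff0": self.ff0_init,
            "de_dr": self.fds_init.de_dr,
            "de_dt": self.fds_init.de_dt,
            "delta": self.fds_init.delta,
            "sigma": self.fds_init.sigma,
        }
        converged = True
        n_iter = 0
        if names:
            tf = _BoxTransform([self.bounds[n] for n in names])
            x0 = tf.to_x(np.array([init_map[n] for n in names]))

            def fun(x):
                return self.objective(names, tf.to_p(x))

            f0 = fun(x0)
            res = optimize.minimize(
                fun,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "xatol": xatol,
                    "fatol": max(fatol_rel * max(f0, 1e-30), 1e-14),
                    "adaptive": len(names) > 3,
                },
            )
            best = tf.to_p(res.x)
            converged = bool(res.success)
            n_iter = int(res.nit)
            if not converged:
                logger.warning(
                    "outer optimizer did not converge (%s); returning best-so-far",
                    res.message,
                )
        else:
            best = np.array([])

        cell, ff0, fds = self._params_from_vector(names, best)
        basis = self.build_basis(cell, ff0, fds)
        if self.reg_alpha == "auto":
            alpha = select_regularization(
                self.Y_fitspace, basis, self.fit_ti, self.fit_ri
            )
        else:
            alpha = float(self.reg_alpha)
        sub = solve_linear_subproblem(
            self.Y_fitspace, basis, alpha, self.fit_ti, self.fit_ri
        )
        cs = CsModel(
            s_grid=self.s_grid,
            ff0=ff0,
            amplitudes=sub.amplitudes,
            reg_alpha=alpha,
            ti=sub.ti,
            ri=sub.ri,
        )
        # residuals and rmsd reported over the raw data space
        fitted_linear = sub.model + sub.ti[None, :] + sub.ri[:, None]
        if self.nonlinearity is not None:
            fitted_raw = delinearize_signal(fitted_linear, self.nonlinearity)
        else:
            fitted_raw = fitted_linear
        residuals = self.Y - fitted_raw
        rmsd = float(np.sqrt(np.mean(residuals**2)))

        s_w, amplitude = integrate_cs(cs)
        if np.isfinite(s_w) and s_w > 0:
            D_w = diffusion_from_ff0(s_w * SVEDBERG, ff0, self.conditions)
            mw = svedberg_mass(s_w * SVEDBERG, D_w, self.conditions)
        else:
            mw = float("nan")
        return CsFitResults(
            model=self,
            params=dict(zip(names, best)),
            cell_model=cell,
            ff0=ff0,
            fds=fds,
            cs=cs,
            rmsd=rmsd,
            rmsd_fitspace=sub.rmsd,
            s_w=s_w,
            boundary_amplitude=amplitude,
            mw_app_kda=mw,
            residuals=residuals,
            fitted=fitted_raw,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class CsFitResults:
    """Results of a :class:`CsFit` refinement."""

    model: CsFit
    params: dict
    cell_model: CellModel
    ff0: float
    fds: FdsParams
    cs: CsModel
    rmsd: float
    rmsd_fitspace: float
    s_w: float
    boundary_amplitude: float
    mw_app_kda: float
    residuals: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int = 0

    def report(
        self,
        run_id: str = "",
        cell: int | None = None,
        gain: int | None = None,
        focal_depth_um: float | None = None,
    ) -> FitReport:
        """Package the results as a :class:`FitReport` for summary tables."""
        ss = self.model.scanset
        return FitReport(
            fds=self.fds,
            cell_model=self.cell_model,
            ff0=self.ff0,
            rmsd=self.rmsd,
            s_w=self.s_w,
            boundary_amplitude=self.boundary_amplitude,
            mw_app_kda=self.mw_app_kda,
            cs=self.cs,
            residuals=self.residuals,
            run_id=run_id or (ss.run_id if ss else ""),
            cell=cell if cell is not None else (ss.cell if ss else 1),
            gain=gain if gain is not None else (ss.gain if ss else 1),
            focal_depth_um=(
                focal_depth_um
                if focal_depth_um is not None
                else (ss.focal_depth_um if ss else None)
            ),
            converged=self.converged,
        )

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "c(s) direct boundary fit (FDS signal model)",
            "=" * 47,
            f"{'scans x radii':<24}{self.residuals.shape[0]} x {self.residuals.shape[1]}",
            f"{'rmsd (counts)':<24}{self.rmsd:.6g}",
            f"{'s_w (S)':<24}{self.s_w:.6g}",
            f"{'boundary amplitude':<24}{self.boundary_amplitude:.6g}",
            f"{'f/f0':<24}{self.ff0:.4f}",
            f"{'apparent MW (kDa)':<24}{self.mw_app_kda:.4g}",
            f"{'meniscus (cm)':<24}{self.cell_model.meniscus:.4f}",
            f"{'bottom (cm)':<24}{self.cell_model.bottom:.4f}",
            f"{'de/dr (1/cm)':<24}{self.fds.de_dr:.5g}",
            f"{'de/dt (1/h)':<24}{self.fds.de_dt:.5g}",
            f"{'delta (cm)':<24}{self.fds.delta:.5g}",
            f"{'sigma (cm)':<24}{self.fds.sigma:.5g}",
            f"{'reg. alpha':<24}{self.cs.reg_alpha:.4g}",
            f"{'converged':<24}{self.converged}",
        ]
        return "\n".join(lines)


def fit_cs(data: ScanSet, cell: CellModel, **kwargs) -> FitReport:
    """Convenience wrapper: build a :class:`CsFit`, fit, return a report."""
    fit_kwargs = {}
    for key in ("maxiter", "xatol", "fatol_rel"):
        if key in kwargs:
            fit_kwargs[key] = kwargs.pop(key)
    return CsFit(data, cell, **kwargs).fit(**fit_kwargs).report()
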