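"""Batch fitting and cross-run analyses: gain linearity, signal increments,
beam-angle regression.

After a serial c(s) analysis of every (cell, gain) group, the boundary
amplitudes a_b(c, g) of a cell measured at gains g are regressed against g;
the slope a_b*(c) = d a_b / d g is the average boundary height normalized
to a gain of unity.  Dividing by the loading concentration yields the
effective signal increment eps*(c) = a_b*(c)/c in counts per nM, whose
decrease with concentration is the signature of inner-filter
non-linearity.  Finally, the growth of the fitted beam half-width delta
with focal depth z gives an effective beam angle atan(d delta / d z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundary_fit import FitReport, fit_cs
from .lamm_core import CellModel
from .scan_io import ScanSet, write_summary

logger = logging.getLogger(__name__)


@dataclass
class GainSeries:
    """Boundary amplitude versus gain for one cell.

    ``slope`` / ``intercept`` are the free-intercept ordinary least-squares
    fit of a_b against g; ``slope_zero_intercept`` forces the line through
    the origin.  ``residual_fraction`` is the rms residual of the free fit
    divided by the mean amplitude.
    """

    cell: int
    gains: np.ndarray
    amplitudes: np.ndarray
    slope: float
    intercept: float
    slope_zero_intercept: float
    residual_fraction: float
    focal_depth_um: float | None = None
    run_id: str = ""


@dataclass
class IncrementSurface:
    """Effective signal increment eps*(c) per (concentration, focal depth)."""

    table: pd.DataFrame  # columns concentration_nM, focal_depth_um, eps_star
    nonlinearity_flag: bool = False


def serial_fit(
    groups: dict[tuple[int, int], ScanSet],
    cell: CellModel,
    summary_path=None,
    **fit_kwargs,
) -> list[FitReport]:
    """Fit every (cell, gain) group and optionally write the summary CSV.

    Failures of individual groups are logged and skipped, mirroring an
    unattended overnight batch; an empty result raises.
    """
    if not groups:
        raise ValueError("no scan groups to fit")
    reports: list[FitReport] = []
    for (cell_id, gain), scanset in sorted(groups.items()):
        try:
            rep = fit_cs(scanset, cell, **fit_kwargs)
            rep.cell = cell_id
            rep.gain = gain
            rep.run_id = rep.run_id or scanset.run_id
            rep.focal_depth_um = scanset.focal_depth_um
            reports.append(rep)
        except Exception:
            logger.exception("fit failed for cell=%s gain=%s; skipping", cell_id, gain)
    if not reports:
        raise RuntimeError("all serial fits failed")
    if summary_path is not None:
        write_summary(reports, summary_path)
    return reports


def gain_linearity(reports: list[FitReport]) -> list[GainSeries]:
    """Regress boundary amplitude against gain, per cell.

    Requires at least two distinct gains per cell.  The fitted slope is
    invariant under permutation of the inputs.
    """
    by_cell: dict[int, list[FitReport]] = {}
    for rep in reports:
        by_cell.setdefault(rep.cell, []).append(rep)
    out = []
    for cell_id, reps in sorted(by_cell.items()):
        g = np.array([r.gain for r in reps], dtype=float)
        a = np.array([r.boundary_amplitude for r in reps], dtype=float)
        if np.unique(g).size < 2:
            raise ValueError(f"cell {cell_id}: need >=2 distinct gains for a slope")
        order = np.argsort(g)
        g, a = g[order], a[order]
        slope, intercept = np.polyfit(g, a, 1)
        resid = a - (slope * g + intercept)
        mean_amp = float(np.mean(a))
        res_frac = float(np.sqrt(np.mean(resid**2)) / mean_amp) if mean_amp else np.inf
        slope0 = float(np.sum(g * a) / np.sum(g * g))
        out.append(
            GainSeries(
                cell=cell_id,
                gains=g,
                amplitudes=a,
                slope=float(slope),
                intercept=float(intercept),
                slope_zero_intercept=slope0,
                residual_fraction=res_frac,
                focal_depth_um=reps[0].focal_depth_um,
                run_id=reps[0].run_id,
            )
        )
    return out


def increment_surface(
    series: list[GainSeries],
    concentrations: dict[int, float],
    focal_depths: dict[int, float] | None = None,
) -> IncrementSurface:
    """Normalize gain-slopes by loading concentration: eps*(c) = a_b*(c)/c.

    ``concentrations`` maps cell id to loading concentration in nM (user
    metadata, never inferred from the signal).  A strictly monotone
    decrease of eps* with concentration raises the non-linearity flag (the
    inner-filter signature); a single concentration never flags.
    """
    rows = []
    for gs in series:
        c = concentrations[gs.cell]
        if c <= 0:
            raise ValueError(f"cell {gs.cell}: concentration must be positive")
        z = gs.focal_depth_um
        if focal_depths is not None and gs.cell in focal_depths:
            z = focal_depths[gs.cell]
        rows.append(
            {
                "cell": gs.cell,
                "concentration_nM": c,
                "focal_depth_um": z,
                "eps_star": gs.slope / c,
            }
        )
    table = pd.DataFrame(rows).sort_values("concentration_nM", ignore_index=True)
    flag = False
    if len(table) > 1:
        eps = table["eps_star"].to_numpy()
        flag = bool(np.all(np.diff(eps) < 0))
    return IncrementSurface(table=table, nonlinearity_flag=flag)


def beam_angle(focal_depths_um, deltas_cm) -> float:
    """Effective beam angle from the growth of delta with focal depth.

    Least-squares slope of the beam half-width delta (cm) against focal
    depth z (um, converted to cm); returns atan(d delta/d z) in degrees.
    """
    z = np.asarray(focal_depths_um, dtype=float) * 1e-4  # um -> cm
    d = np.asarray(deltas_cm, dtype=float)
    if z.size < 2 or d.size != z.size:
        raise ValueError("need >=2 paired (focal depth, delta) values")
    if np.ptp(z) == 0:
        raise ValueError("focal depths are degenerate")
    slope, _ = np.polyfit(z, d, 1)
    return float(np.degrees(np.arctan(slope)))
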