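"""Reading and writing of radial scan files, list files and summary tables.

The on-disk scan dialect follows the de-facto AUC interchange convention of
Beckman XL-A-style text files: a free-form title line, a header line with
``type-letter cell temperature rpm time [w2t]``, then whitespace-separated
numeric columns radius / signal [/ per-point standard deviation].  Gain,
channel and acquisition metadata that the classic header has no field for
are carried as ``key=value`` tokens on the title line.

List files group scan paths (one per line, ``#`` comments) per sector and
gain so that data sets with scans at a given time span and interval can be
loaded in one call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class ScanFormatError(ValueError):
    """A scan or list file that cannot be parsed."""


@dataclass
class RadialScan:
    """One timestamped radial fluorescence trace.

    ``radii`` are physical cm from the rotor center (strictly increasing,
    typically 0.002 cm spacing); ``signal`` is in detector counts; ``time``
    is elapsed seconds since the start of centrifugation.
    """

    radii: np.ndarray
    signal: np.ndarray
    time: float
    rpm: float
    temperature: float = 20.0
    cell: int = 1
    gain: int = 1
    channel: str = "A"
    stderr: np.ndarray | None = None
    w2t: float | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
        if self.radii.size == 0:
            raise ValueError("scan must contain at least one data point")
        if self.radii.size != self.signal.size:
            raise ValueError("radii and signal must have equal length")
        if self.stderr is not None and self.stderr.size != self.radii.size:
            raise ValueError("stderr column must match the radii length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def n_points(self) -> int:
        return self.radii.size


@dataclass
class ScanSet:
    """An ordered collection of scans from one sector at one gain."""

    scans: list[RadialScan]
    focal_depth_um: float | None = None
    pmt: float | None = None
    run_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("ScanSet must contain at least one scan")
        cells = {s.cell for s in self.scans}
        gains = {s.gain for s in self.scans}
        if len(cells) > 1 or len(gains) > 1:
            raise ValueError(
                f"all scans in a ScanSet must share cell and gain "
                f"(got cells {sorted(cells)}, gains {sorted(gains)})"
            )
        times = [s.time for s in self.scans]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("scan times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def cell(self) -> int:
        return self.scans[0].cell

    @property
    def gain(self) -> int:
        return self.scans[0].gain

    @property
    def rpm(self) -> float:
        return self.scans[0].rpm

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    @property
    def radii(self) -> np.ndarray:
        """Common radial grid; raises if the scans disagree."""
        r0 = self.scans[0].radii
        for s in self.scans[1:]:
            if s.radii.size != r0.size or not np.allclose(s.radii, r0, atol=1e-9):
                raise ValueError("scans do not share a common radial grid")
        return r0

    def signal_matrix(self) -> np.ndarray:
        """Signals stacked as (n_scans, n_radii) on the common grid."""
        _ = self.radii  # validates the common grid
        return np.vstack([s.signal for s in self.scans])


def _parse_title_meta(title: str) -> dict:
    meta = {}
    for tok in title.split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            meta[key.lower()] = val
    return meta


def read_scan(path) -> RadialScan:
    """Read one scan file.

    The first line is a free title (``key=value`` tokens are picked up as
    metadata: cell, gain, channel); the second line must carry at least
    ``type cell temperature rpm time`` with an optional trailing w2t field;
    the remainder are 2-3 numeric columns radius / signal [/ std].
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ScanFormatError(f"{path}: need 2 header lines and data")
    title = lines[0]
    header = lines[1].split()
    if len(header) < 5:
        raise ScanFormatError(
            f"{path}: line 2 must contain 'type cell temperature rpm time [w2t]', "
            f"got {lines[1]!r}"
        )
    try:
        cell = int(header[1])
        temperature = float(header[2])
        rpm = float(header[3])
        time = float(header[4])
        w2t = float(header[5]) if len(header) > 5 else None
    except ValueError as exc:
        raise ScanFormatError(f"{path}: malformed header line 2: {lines[1]!r}") from exc
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ScanFormatError(f"{path}: line {i}: expected >=2 columns")
        try:
            rows.append([float(p) for p in parts[:3]])
        except ValueError as exc:
            raise ScanFormatError(f"{path}: line {i}: non-numeric data") from exc
    if len(rows) < 2:
        raise ScanFormatError(f"{path}: fewer than 2 data points")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    meta = _parse_title_meta(title)
    return RadialScan(
        radii=arr[:, 0],
        signal=arr[:, 1],
        stderr=arr[:, 2] if ncol >= 3 else None,
        time=time,
        rpm=rpm,
        temperature=temperature,
        cell=int(meta.get("cell", cell)),
        gain=int(meta.get("gain", 1)),
        channel=meta.get("channel", "A"),
        w2t=w2t,
        title=title,
    )


def write_scan(scan: RadialScan, path) -> None:
    """Write a scan in the dialect read back by :func:`read_scan`.

    Values are written with 15 significant digits so a read/write round
    trip is lossless well below 1e-12 relative.
    """
    path = Path(path)
    title = scan.title or "fdsvel scan"
    meta_tokens = []
    for key, val in (("cell", scan.cell), ("gain", scan.gain), ("channel", scan.channel)):
        if f"{key}=" not in title:
            meta_tokens.append(f"{key}={val}")
    if meta_tokens:
        title = f"{title} {' '.join(meta_tokens)}"
    w2t = "" if scan.w2t is None else f" {scan.w2t:.10e}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(
            f"F {scan.cell} {scan.temperature:.6g} {scan.rpm:.10g} "
            f"{scan.time:.10g}{w2t}\n"
        )
        if scan.stderr is None:
            for r, s in zip(scan.radii, scan.signal):
                fh.write(f"{r:.15g} {s:.15g}\n")
        else:
            for r, s, e in zip(scan.radii, scan.signal, scan.stderr):
                fh.write(f"{r:.15g} {s:.15g} {e:.15g}\n")


def sort_by_gain(paths, out_dir=None) -> dict[tuple[int, int], ScanSet]:
    """Group scan files into time-ordered ScanSets keyed by (cell, gain).

    Unparsable files are skipped with a logged reason; mixed rotor speeds
    within a group are retained with a warning.  When ``out_dir`` is given,
    one list file per group (``cell{c}_gain{g}.list``) is written there.
    """
    groups: dict[tuple[int, int], list[tuple[RadialScan, Path]]] = {}
    for path in paths:
        try:
            scan = read_scan(path)
        except (ScanFormatError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        groups.setdefault((scan.cell, scan.gain), []).append((scan, Path(path)))

    out: dict[tuple[int, int], ScanSet] = {}
    for key, items in sorted(groups.items()):
        items.sort(key=lambda sp: sp[0].time)
        scans = [s for s, _ in items]
        if len({s.rpm for s in scans}) > 1:
            warnings.warn(
                f"group cell={key[0]} gain={key[1]} mixes rotor speeds; retained",
                stacklevel=2,
            )
        out[key] = ScanSet(scans=scans)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            listfile = out_dir / f"cell{key[0]}_gain{key[1]}.list"
            with open(listfile, "w") as fh:
                fh.write(f"# cell={key[0]} gain={key[1]}\n")
                for _, p in items:
                    fh.write(f"{p}\n")
    return out


def load_listfile(path, every_k: int = 1, t_min: float = 0.0, t_max: float = np.inf) -> ScanSet:
    """Load the scans named in a list file, windowed and thinned.

    Keeps scans with ``t_min <= time <= t_max``, then every ``every_k``-th
    of the survivors (starting with the first).  Raises if the selection is
    empty.  Relative paths are resolved against the list-file directory.
    """
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    path = Path(path)
    scans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = Path(line)
            if not p.is_absolute():
                p = path.parent / p
            scans.append(read_scan(p))
    scans.sort(key=lambda s: s.time)
    kept = [s for s in scans if t_min <= s.time <= t_max]
    kept = kept[::every_k]
    if not kept:
        raise ValueError(
            f"{path}: no scans in time window [{t_min}, {t_max}] after thinning"
        )
    return ScanSet(scans=kept)


#: Fixed column set of the batch summary table.
SUMMARY_COLUMNS = [
    "run",
    "cell",
    "gain",
    "focal_depth_um",
    "rmsd",
    "s_w",
    "boundary_amplitude",
    "ff0",
    "mw_kda",
    "de_dr",
    "de_dt",
    "delta",
    "sigma",
    "meniscus",
    "bottom",
]


def write_summary(reports, path) -> None:
    """Write one CSV row per fit report with the fixed column set."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "run": rep.run_id,
                "cell": rep.cell,
                "gain": rep.gain,
                "focal_depth_um": rep.focal_depth_um,
                "rmsd": rep.rmsd,
                "s_w": rep.s_w,
                "boundary_amplitude": rep.boundary_amplitude,
                "ff0": rep.ff0,
                "mw_kda": rep.mw_app_kda,
                "de_dr": rep.fds.de_dr,
                "de_dt": rep.fds.de_dt,
                "delta": rep.fds.delta,
                "sigma": rep.fds.sigma,
                "meniscus": rep.cell_model.meniscus,
                "bottom": rep.cell_model.bottom,
            }
        )
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    """Read a summary CSV back into a DataFrame (columns as written)."""
    return pd.read_csv(path)


def read_config(path) -> dict:
    """Read a YAML run-configuration file.

    Recognized keys (all optional, with analysis defaults): density [g/ml],
    viscosity [poise], vbar [ml/g], temperature [K], meniscus, bottom [cm],
    s_min, s_max [S], n_s, float (list of parameter names), and initial
    detector parameters de_dr, de_dt, delta, sigma, a0, kappa.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ScanFormatError(f"{path}: config must be a YAML mapping")
    return cfg
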