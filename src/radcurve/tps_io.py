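"""Reading and writing TPS landmark files and group/angle tables.

The TPS dialect accepted here is the one produced by the tps* family of
digitizing tools: each record starts with an ``LM=<k>`` header, followed by
``k`` whitespace-separated coordinate lines, optionally followed by ``ID=``,
``IMAGE=`` and ``SCALE=`` lines.  Coordinates are y-up Cartesian (digitizer
convention), not image row/column.  ``SCALE=`` multiplies the raw pixel
coordinates on read; scale is consumed at read time and never re-emitted, so a
write/read round trip is the identity on the stored coordinates.

Outlines follow the 21-point convention used throughout the package: one fixed
landmark (index 0, digitized at the middle of the ulnar articular surface)
plus 20 sliding semi-landmarks spaced equally by arc length, traversed
clockwise (negative signed area).  Right-side specimens are mirrored to
left-equivalent form at load time so all downstream shape analysis sees a
single handedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenRecord",
    "read_tps",
    "write_tps",
    "resample_outline",
    "mirror_configuration",
    "signed_area",
    "read_group_table",
    "stack_configurations",
    "load_dataset",
]


class TPSParseError(ValueError):
    """Raised when a TPS file is malformed; message names the record index."""


@dataclass
class LandmarkConfiguration:
    """An ordered 2D outline: ``k`` points with one designated fixed landmark.

    Point order is the digitization order (clockwise from the fixed
    landmark).  Coordinates are dimensionless after scaling.
    """

    points: np.ndarray
    fixed_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if pts.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        if not 0 <= self.fixed_index < pts.shape[0]:
            raise ValueError("fixed_index out of range")
        self.points = pts

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class SpecimenRecord:
    specimen_id: str
    configuration: LandmarkConfiguration
    taxon: str = ""
    side: str = "unknown"  # left | right | unknown
    image_scale: float | None = None
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.image_scale is not None and self.image_scale <= 0:
            raise ValueError("image_scale must be positive")


def read_tps(path: str | Path) -> list[SpecimenRecord]:
    """Parse a TPS file into one :class:`SpecimenRecord` per LM record."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    records: list[SpecimenRecord] = []
    i = 0
    rec_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(
                f"record {rec_idx}: expected 'LM=' header, got {line!r}"
            )
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {rec_idx}: malformed header {line!r}") from exc
        i += 1
        coords = []
        while len(coords) < k and i < len(lines):
            tok = lines[i].strip()
            if not tok:
                i += 1
                continue
            if "=" in tok and not _looks_numeric(tok.split()[0]):
                break
            parts = tok.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {rec_idx}: expected 2 coordinates, got {tok!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"record {rec_idx}: non-numeric coordinate {tok!r}"
                ) from exc
            i += 1
        if len(coords) != k:
            raise TPSParseError(
                f"record {rec_idx}: LM={k} but found {len(coords)} coordinate lines"
            )
        specimen_id = f"specimen_{rec_idx}"
        scale = None
        while i < len(lines):
            tok = lines[i].strip()
            if not tok:
                i += 1
                continue
            if tok.upper().startswith("LM="):
                break
            if "=" not in tok:
                raise TPSParseError(f"record {rec_idx}: unexpected line {tok!r}")
            key, _, value = tok.partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key == "IMAGE":
                pass
            else:
                warnings.warn(f"record {rec_idx}: ignoring unknown TPS key {key!r}")
            i += 1
        pts = np.asarray(coords, dtype=float)
        if scale is not None:
            pts = pts * scale
        records.append(
            SpecimenRecord(
                specimen_id=specimen_id,
                configuration=LandmarkConfiguration(pts),
                image_scale=scale,
            )
        )
        rec_idx += 1
    return records


def _looks_numeric(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_tps(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    """Write records as TPS text (LM= and ID= lines; coordinates as stored)."""
    if len(records) == 0:
        raise ValueError("cannot write an empty record list")
    out = []
    for rec in records:
        pts = rec.configuration.points
        out.append(f"LM={pts.shape[0]}")
        for x, y in pts:
            out.append(f"{x:.17g} {y:.17g}")
        out.append(f"ID={rec.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (y-up: clockwise is negative)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_outline(
    raw_points: np.ndarray,
    n_semilandmarks: int = 20,
    start: int = 0,
) -> LandmarkConfiguration:
    """Resample a dense closed polyline to ``n_semilandmarks + 1`` points
    equally spaced by cumulative arc length, point 0 at the start vertex,
    traversed clockwise.

    Counter-clockwise inputs are reversed with a warning.  The first/last
    vertex duplicate, if present, is dropped before wrapping.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("raw_points must be (m, 2)")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    m = pts.shape[0]
    if m < n_semilandmarks + 1:
        raise ValueError("polyline has fewer vertices than output points")
    if not 0 <= start < m:
        raise ValueError("start index out of range")
    pts = np.roll(pts, -start, axis=0)
    if signed_area(pts) > 0:
        warnings.warn("outline is counter-clockwise; reversing to clockwise")
        pts = np.concatenate([pts[:1], pts[:0:-1]], axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polyline: zero total length")
    n_out = n_semilandmarks + 1
    targets = np.arange(n_out) * total / n_out
    out = np.empty((n_out, 2))
    out[0] = pts[0]  # exact start vertex
    idx = np.searchsorted(cum, targets[1:], side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets[1:] - cum[idx]) / seg[idx]
    out[1:] = closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])
    return LandmarkConfiguration(out, fixed_index=0)


def mirror_configuration(c: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect x -> -x; point order and fixed_index unchanged (handedness flips)."""
    pts = c.points.copy()
    pts[:, 0] = -pts[:, 0]
    return LandmarkConfiguration(pts, fixed_index=c.fixed_index)


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 CSV group table with a header row.

    Required column: ``specimen_id``.  Optional: ``taxon``, ``side``, plus one
    column per grouping scheme.  Returns a DataFrame indexed by specimen_id.
    """
    df = pd.read_csv(path, encoding="utf-8", dtype={"specimen_id": str})
    if "specimen_id" not in df.columns:
        raise ValueError("group table must have a 'specimen_id' column")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id values: {dupes}")
    return df.set_index("specimen_id")


def stack_configurations(records: Iterable[SpecimenRecord]) -> np.ndarray:
    """Stack configurations into an (n, k, 2) array; all k must match."""
    mats = [r.configuration.points for r in records]
    ks = {m.shape[0] for m in mats}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
    return np.stack(mats, axis=0)


def load_dataset(
    tps_path: str | Path,
    group_csv: str | Path | None = None,
) -> tuple[list[SpecimenRecord], pd.DataFrame | None]:
    """Load TPS records, merge taxon/side metadata, mirror right-side specimens.

    Mirroring standardizes every configuration to left-equivalent form so that
    rotation-only superimposition (no reflection) is valid downstream.
    """
    records = read_tps(tps_path)
    table = None
    if group_csv is not None:
        table = read_group_table(group_csv)
        merged = []
        for rec in records:
            if rec.specimen_id in table.index:
                row = table.loc[rec.specimen_id]
                side = str(row.get("side", "unknown") or "unknown")
                taxon = str(row.get("taxon", "") or "")
                rec = replace(rec, side=side, taxon=taxon)
            merged.append(rec)
        records = merged
    out = []
    for rec in records:
        if rec.side == "right" and not rec.mirrored:
            rec = replace(
                rec,
                configuration=mirror_configuration(rec.configuration),
                mirrored=True,
            )
        out.append(rec)
    return out, table
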