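"""Angle-of-curvature metric for the radius.

The metric relates the plane of the radial head to the long axis of the
shaft using three digitized points: one at the lateral distal end of the
radius, one at the proximal lateral radial head (the vertex), and one across
the radial head to the medial surface.  The reported angle is the interior
angle at the vertex between the vectors to the other two points, in degrees.
An angle of 90 degrees indicates a straight radius unable to cross the ulna;
departures from 90 degrees indicate a curved radius able to cross the ulna.

The vertex is fixed at the radial-head corner shared by the two vectors: the
published description places the distal point laterally in the text and
medially in the figure caption, but either reading leaves the vertex at the
proximal radial-head point, which is what the computation uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleRecord",
    "angle_of_curvature",
    "classify_curvature",
    "read_angle_table",
]


@dataclass
class AngleRecord:
    """Three digitized points (pixels) and, once computed, the angle in degrees."""

    specimen_id: str
    p_distal: tuple[float, float]
    p_head_lateral: tuple[float, float]  # vertex
    p_head_medial: tuple[float, float]
    angle_deg: float | None = None


def angle_of_curvature(record: AngleRecord | None = None, *, p_distal=None, vertex=None, p_head_medial=None) -> float:
    """Interior angle at the radial-head vertex, in degrees, in (0, 180].

    Invariant under rotation, translation, uniform scaling and mirroring of
    the three points.  Coincident points are rejected.
    """
    if record is not None:
        p_distal = record.p_distal
        vertex = record.p_head_lateral
        p_head_medial = record.p_head_medial
    a = np.asarray(p_distal, dtype=float)
    v = np.asarray(vertex, dtype=float)
    b = np.asarray(p_head_medial, dtype=float)
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0 or n2 == 0 or np.allclose(a, b):
        raise ValueError("angle undefined: coincident points")
    dot = float(u1 @ u2)
    cross = abs(float(u1[0] * u2[1] - u1[1] * u2[0]))
    ang = np.degrees(np.arctan2(cross, dot))
    if record is not None:
        record.angle_deg = float(ang)
    return float(ang)


def classify_curvature(angle_deg: float, tolerance_deg: float = 0.0) -> str:
    """'straight' iff |angle - 90| <= tolerance (closed interval), else 'curved'."""
    if not 0 < angle_deg <= 180:
        raise ValueError("angle must be in (0, 180] degrees")
    if tolerance_deg < 0:
        raise ValueError("tolerance must be non-negative")
    return "straight" if abs(angle_deg - 90.0) <= tolerance_deg else "curved"


def read_angle_table(path):
    """Read an angle CSV; derive ``angle_deg`` from digitized points if needed.

    Accepts either a pre-measured ``angle_deg`` column or the six coordinate
    columns ``distal_x, distal_y, vertex_x, vertex_y, medial_x, medial_y``
    (the three digitized points), from which the angle is computed per row.
    Returns a DataFrame with ``specimen_id`` and ``angle_deg``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        needed = ["distal_x", "distal_y", "vertex_x", "vertex_y", "medial_x", "medial_y"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(
                f"angle table needs 'angle_deg' or point columns; missing {missing}"
            )
        df["angle_deg"] = [
            angle_of_curvature(
                p_distal=(r.distal_x, r.distal_y),
                vertex=(r.vertex_x, r.vertex_y),
                p_head_medial=(r.medial_x, r.medial_y),
            )
            for r in df.itertuples()
        ]
    return df
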