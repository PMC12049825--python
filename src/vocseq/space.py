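"""Change geometry of consecutive calls in 2-D acoustic planes.

Each call occupies a point in two standard planes:

* **activation**  — (duration_s, maxfreq_hz): when/how strongly the source
  engages;
* **modulation**  — (freqslope_hz, entropy_bits): how the source's
  oscillation changes within the call.

For every pair of consecutive calls we form a displacement vector, either
in raw parameter units ("absolute" mode) or as signed percentages of the
current value ("percent" mode).  Three summaries are derived: per-cell
direction maps on a grid over the plane (which way does the voice move out
of each region of acoustic space, and how far), and angular "pizza-slice"
summaries of displacement magnitude (median and 2.5/97.5 percentiles of
distance from origin per angular sector).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import CallSequence

logger = logging.getLogger(__name__)

#: Compass names of the 8 direction sectors, 45 degrees each, centred on
#: 0, 45, ..., 315 degrees (east = increasing x, north = increasing y).
DIRECTION_SECTORS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")


@dataclass(frozen=True)
class PlaneSpec:
    """A 2-D acoustic plane with a rectangular analysis grid.

    The grid defaults to 10x10 bins over the observed min-max of each
    parameter (set ``x_range``/``y_range`` to pin explicit limits).  Bins
    are half-open except the last, which is closed so the maximum falls in
    the top bin.  ``clip`` controls what happens to calls outside an
    explicit range: ``"clip"`` snaps them to the edge cell, ``"error"``
    raises.
    """

    x_param: str
    y_param: str
    x_bins: int = 10
    y_bins: int = 10
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    clip: Literal["clip", "error"] = "clip"

    def __post_init__(self):
        if self.x_bins < 2 or self.y_bins < 2:
            raise ValueError("bin counts must be >= 2")


#: The two planes of the standard analysis.
ACTIVATION_PLANE = PlaneSpec(x_param="duration_s", y_param="maxfreq_hz")
MODULATION_PLANE = PlaneSpec(x_param="freqslope_hz", y_param="entropy_bits")


@dataclass(frozen=True)
class ChangeVector:
    """Displacement between two consecutive calls in one plane.

    ``dx``/``dy`` are signed differences (absolute mode, parameter units)
    or signed percentages (percent mode).  ``angle`` is in degrees in
    [0, 360), measured counter-clockwise from the positive x axis, and is
    ``nan`` when the displacement is zero.  In percent mode a zero current
    value makes the axis undefined: the vector is flagged and excluded
    from slice summaries.
    """

    from_call: int
    to_call: int
    dx: float
    dy: float
    distance: float
    angle: float
    defined: bool = True


def _displacement(dx: float, dy: float) -> tuple[float, float]:
    distance = math.hypot(dx, dy)
    angle = math.degrees(math.atan2(dy, dx)) % 360.0 if distance > 0 else math.nan
    return distance, angle


def change_vectors(
    seq: CallSequence,
    plane: PlaneSpec,
    mode: Literal["absolute", "percent"] = "absolute",
) -> list[ChangeVector]:
    """Displacements between the n-1 consecutive call pairs of a sequence.

    Percent mode uses ``100 * (next - current) / |current|`` per axis, so
    the sign of the change is preserved even when the current value is
    negative (relevant for frequency-contour slopes).
    """
    if len(seq) < 2:
        raise ValueError("change_vectors requires a sequence of length >= 2")
    x = seq.param(plane.x_param)
    y = seq.param(plane.y_param)
    vectors: list[ChangeVector] = []
    for i in range(len(seq) - 1):
        if mode == "absolute":
            dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
            defined = True
        elif mode == "percent":
            defined = x[i] != 0 and y[i] != 0
            if defined:
                dx = 100.0 * (x[i + 1] - x[i]) / abs(x[i])
                dy = 100.0 * (y[i + 1] - y[i]) / abs(y[i])
            else:
                dx = dy = math.nan
                logger.warning(
                    "percent change undefined at call %d of %s/%s (zero value)",
                    i + 1, seq.subject, seq.session,
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if defined:
            distance, angle = _displacement(dx, dy)
        else:
            distance, angle = math.nan, math.nan
        vectors.append(ChangeVector(i, i + 1, dx, dy, distance, angle, defined))
    return vectors


def vectors_to_frame(vectors: Iterable[ChangeVector]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in vectors])


def direction_sector(angle: float) -> str:
    """Map an angle in degrees to one of the 8 compass sectors.

    Sectors are 45 degrees wide, centred on 0, 45, ..., 315; 'E' covers
    [-22.5, 22.5) and so on counter-clockwise.
    """
    idx = int(math.floor(((angle + 22.5) % 360.0) / 45.0))
    return DIRECTION_SECTORS[idx]


def _bin_index(values: np.ndarray, lo: float, hi: float, n_bins: int,
               clip: str, label: str) -> np.ndarray:
    if hi <= lo:  # degenerate axis: all mass in one cell
        return np.zeros(len(values), dtype=int)
    if clip == "error" and ((values < lo) | (values > hi)).any():
        raise ValueError(f"call outside plane range on {label}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(values, edges[1:-1], right=False)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class DirectionMap:
    """Per-cell outgoing direction counts for one plane.

    ``table`` has one row per (cell_x, cell_y, direction) with the number
    of consecutive-call transitions leaving that cell in that direction
    ('self' marks zero displacement).  When built with the ``distance``
    summary, a ``mean_cell_distance`` column carries the mean Euclidean
    distance travelled, measured in cell units.  The total of ``count``
    equals the number of consecutive-call transitions (n - 1 per n-call
    sequence).
    """

    plane: PlaneSpec
    summary: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total_count(self) -> int:
        return int(self.table["count"].sum()) if len(self.table) else 0


def grid_direction_map(
    seq: CallSequence,
    plane: PlaneSpec,
    summary: Literal["direction", "distance"] = "direction",
) -> DirectionMap:
    """Grid the plane and count the outgoing movement of each cell.

    Every consecutive pair of calls contributes one arrow from the cell of
    the earlier call, categorized into 8 compass sectors (plus 'self' for
    zero displacement).  With ``summary="distance"``, each arrow group also
    reports the mean distance travelled in cell-space units.
    """
    if len(seq) < 2:
        raise ValueError("grid_direction_map requires a sequence of length >= 2")
    x = seq.param(plane.x_param)
    y = seq.param(plane.y_param)
    x_lo, x_hi = plane.x_range if plane.x_range else (x.min(), x.max())
    y_lo, y_hi = plane.y_range if plane.y_range else (y.min(), y.max())
    cx = _bin_index(x, x_lo, x_hi, plane.x_bins, plane.clip, plane.x_param)
    cy = _bin_index(y, y_lo, y_hi, plane.y_bins, plane.clip, plane.y_param)

    rows = []
    for i in range(len(seq) - 1):
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        distance, angle = _displacement(dx, dy)
        sector = "self" if distance == 0 else direction_sector(angle)
        cell_dist = math.hypot(int(cx[i + 1]) - int(cx[i]), int(cy[i + 1]) - int(cy[i]))
        rows.append((int(cx[i]), int(cy[i]), sector, cell_dist))
    df = pd.DataFrame(rows, columns=["cell_x", "cell_y", "direction", "cell_distance"])
    agg = (
        df.groupby(["cell_x", "cell_y", "direction"], sort=True)
        .agg(count=("cell_distance", "size"), mean_cell_distance=("cell_distance", "mean"))
        .reset_index()
    )
    if summary == "direction":
        agg = agg.drop(columns="mean_cell_distance")
    elif summary != "distance":
        raise ValueError(f"unknown summary {summary!r}")
    return DirectionMap(plane=plane, summary=summary, table=agg)


def slice_summary(
    vectors: Sequence[ChangeVector],
    n_slices: int = 8,
) -> pd.DataFrame:
    """Angular "pizza-slice" summary of displacement magnitudes.

    Vectors are partitioned by angle into ``n_slices`` equal sectors
    starting at 0 degrees; per non-empty slice the count, median distance
    from origin and the 2.5%/97.5% percentiles of distance are reported
    (linear-interpolation quantiles).  Vectors flagged undefined, and
    zero-distance vectors (no angle), are excluded.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    usable = [v for v in vectors if v.defined and v.distance > 0]
    if not usable:
        return pd.DataFrame(
            columns=["slice", "angle_lo", "angle_hi", "count", "median_distance",
                     "p2_5", "p97_5"]
        )
    width = 360.0 / n_slices
    angles = np.array([v.angle for v in usable])
    dists = np.array([v.distance for v in usable])
    idx = np.minimum((angles // width).astype(int), n_slices - 1)
    rows = []
    for s in sorted(set(idx)):
        d = dists[idx == s]
        rows.append(
            (
                int(s),
                s * width,
                (s + 1) * width,
                int(d.size),
                float(np.median(d)),
                float(np.percentile(d, 2.5)),
                float(np.percentile(d, 97.5)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["slice", "angle_lo", "angle_hi", "count", "median_distance",
                 "p2_5", "p97_5"],
    )


def pooled_change_vectors(
    seqs: Sequence[CallSequence],
    plane: PlaneSpec,
    mode: Literal["absolute", "percent"] = "absolute",
    by: Literal["all", "subject", "session"] = "all",
) -> dict[str, list[ChangeVector]]:
    """Change vectors pooled at one of the study's three comparison levels.

    ``by="all"`` pools every sequence into one group (the "across
    subjects" column of the standard figures), ``by="subject"`` groups per
    subject, and ``by="session"`` keeps each (subject, session) separate.
    Vectors never span a sequence boundary.
    """
    groups: dict[str, list[ChangeVector]] = {}
    for seq in seqs:
        if by == "all":
            key = "all"
        elif by == "subject":
            key = seq.subject
        elif by == "session":
            key = f"{seq.subject}/{seq.session}"
        else:
            raise ValueError(f"unknown pooling level {by!r}")
        groups.setdefault(key, []).extend(change_vectors(seq, plane, mode))
    return groups
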