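"""Screen-position handling: regions, hexagonal binning, count tables.

The spatial location of a binocular fixation is the right eye's mean
position during the fixation (for these purposes the choice of eye is
immaterial; both eyes fixate within a character or so of each other).  The
screen is split into left / middle / right regions — by default equal
thirds of the width; the boundaries are configurable because text extent
differs between orthographies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .events import ScreenGeometry

REGIONS = ("left", "middle", "right")


def pair_position(pairs: pd.DataFrame) -> pd.DataFrame:
    """The (x, y) screen position of each pair: the right eye's mean coords."""
    return pairs[["x_px", "y_px"]]


def assign_region(x_px, geometry: ScreenGeometry):
    """Map x-coordinates to the left / middle / right screen region.

    ``left`` if x < bound1, ``middle`` if bound1 <= x < bound2, ``right``
    if x >= bound2.  Coordinates outside [0, width] are an error.
    """
    x = np.asarray(x_px, dtype=float)
    if np.any(x < 0) or np.any(x > geometry.width_px):
        raise ValueError("x coordinate outside the screen")
    b1, b2 = geometry.region_bounds
    idx = np.where(x < b1, 0, np.where(x < b2, 1, 2))
    labels = np.array(REGIONS)[idx]
    if np.ndim(labels) == 0:
        return str(labels)
    return labels


def assign_regions(pairs: pd.DataFrame, geometry: ScreenGeometry) -> pd.DataFrame:
    """Annotate a pairs table with its ``region`` column (from x only)."""
    out = pairs.copy()
    out["region"] = assign_region(out["x_px"].to_numpy(float), geometry)
    return out


@dataclasses.dataclass
class HexbinGrid:
    """Counts on a pointy-top hexagonal tessellation in axial coordinates.

    ``hex_radius_px`` is the center-to-vertex distance.  Cell (q, r) has
    center ``origin + (R*sqrt(3)*(q + r/2), R*1.5*r)``.  Every point is
    assigned to its nearest hex center (the hexagons are the Voronoi cells
    of their centers, so cube-rounding the fractional axial coordinates is
    an exact nearest-center rule).
    """

    hex_radius_px: float
    origin: tuple[float, float]
    cells: dict[tuple[int, int], int]

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def center(self, q: int, r: int) -> tuple[float, float]:
        R = self.hex_radius_px
        return (
            self.origin[0] + R * np.sqrt(3.0) * (q + r / 2.0),
            self.origin[1] + R * 1.5 * r,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"q": q, "r": r, "x_px": self.center(q, r)[0],
             "y_px": self.center(q, r)[1], "count": c}
            for (q, r), c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["q", "r", "x_px", "y_px", "count"])


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # cube rounding: round (q, r, s=-q-r) and fix the coordinate with the
    # largest rounding error so q+r+s == 0
    sf = -qf - rf
    q = np.rint(qf)
    r = np.rint(rf)
    s = np.rint(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


def hexbin_counts(
    points: np.ndarray | pd.DataFrame,
    hex_radius_px: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> HexbinGrid:
    """Bin points into a pointy-top hexagonal grid by nearest center."""
    if hex_radius_px <= 0:
        raise ValueError("hex_radius_px must be positive")
    if isinstance(points, pd.DataFrame):
        pts = points[["x_px", "y_px"]].to_numpy(float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points to bin")
    R = hex_radius_px
    x = pts[:, 0] - origin[0]
    y = pts[:, 1] - origin[1]
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / R
    rf = (2.0 / 3.0 * y) / R
    q, r = _axial_round(qf, rf)
    cells: dict[tuple[int, int], int] = {}
    for qi, ri in zip(q.tolist(), r.tolist()):
        cells[(qi, ri)] = cells.get((qi, ri), 0) + 1
    return HexbinGrid(hex_radius_px=float(R), origin=tuple(origin), cells=cells)


def count_table(pairs: pd.DataFrame, complete_zeros: bool = False) -> pd.DataFrame:
    """Aggregate classified, region-annotated pairs into the modeling table.

    One record per (participant, article, page, region, type) with its
    count.  With ``complete_zeros`` the region × type grid is completed
    with zero counts within every observed page (needed when the models
    should see structural zeros).
    """
    for col in ("type", "region"):
        if col not in pairs.columns or pairs[col].isna().any():
            raise ValueError(f"pairs must carry a complete '{col}' column")
    keys = ["participant_id", "group", "article_id", "page_id", "region", "type"]
    counts = (
        pairs.groupby(keys, sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    if complete_zeros:
        from .typology import LABELS

        pages = pairs[["participant_id", "group", "article_id", "page_id"]].drop_duplicates()
        grid = pages.merge(pd.DataFrame({"region": list(REGIONS)}), how="cross").merge(
            pd.DataFrame({"type": list(LABELS)}), how="cross"
        )
        counts = grid.merge(counts, on=keys, how="left").fillna({"count": 0})
        counts["count"] = counts["count"].astype(int)
        counts = counts.sort_values(keys, kind="mergesort").reset_index(drop=True)
    return counts


def plot_hexbin(grid: HexbinGrid, ax=None, title: str | None = None):
    """Render a hexbin grid as filled hexagons colored by count."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import RegularPolygon

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    patches, vals = [], []
    for (q, r), c in grid.cells.items():
        cx, cy = grid.center(q, r)
        patches.append(
            RegularPolygon((cx, cy), numVertices=6, radius=grid.hex_radius_px)
        )
        vals.append(c)
    coll = PatchCollection(patches, cmap="viridis")
    coll.set_array(np.asarray(vals, dtype=float))
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.invert_yaxis()  # screen coordinates: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if title:
        ax.set_title(title)
    plt.colorbar(coll, ax=ax, label="fixation pairs")
    return ax
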