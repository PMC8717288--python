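"""Domain types for transect stem maps.

A stem map is a marked point pattern observed in a union of long, narrow
rectangles (one per inventory transect).  Stems carry a species code, a
regeneration guild (light-response class) and a dbh mark in centimetres;
subplot tables describe the 25 m x 50 m survey units with their
environmental covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GUILDS = ("SLP", "LLP", "NPLD", "STS")
TOPOGRAPHY_CATEGORIES = ("flat", "slope", "crest", "shallow")

#: minimum stem diameter (cm) recorded by the survey protocol
DBH_THRESHOLD_CM = 10.0

STEM_COLUMNS = ["tree_id", "transect_id", "x", "y", "species", "guild", "dbh"]

SUBPLOT_COLUMNS = [
    "subplot_id",
    "transect_id",
    "cx",
    "cy",
    "slope_pct",
    "topography",
    "altitude_m",
    "dist_water_m",
]


class StemDataError(ValueError):
    """Malformed or inconsistent stem-map input."""


@dataclass(frozen=True)
class TransectWindow:
    """Observation window: disjoint axis-aligned rectangles, one per transect.

    Rectangles are stored in a global frame: transect ``k`` occupies
    ``[0, length_k] x [offset_k, offset_k + width_k]``.  Stem-map files use
    coordinates local to their transect; :meth:`to_global` maps them into
    this frame so cross-transect distances are meaningful.
    """

    rectangles: np.ndarray  # (k, 4): x_min, x_max, y_min, y_max
    transect_ids: tuple = field(default=())

    def __post_init__(self):
        rect = np.atleast_2d(np.asarray(self.rectangles, dtype=float))
        if rect.shape[1] != 4:
            raise ValueError("rectangles must have columns x_min, x_max, y_min, y_max")
        if np.any(rect[:, 1] <= rect[:, 0]) or np.any(rect[:, 3] <= rect[:, 2]):
            raise ValueError("degenerate rectangle in window")
        object.__setattr__(self, "rectangles", rect)
        ids = self.transect_ids or tuple(f"T{i + 1}" for i in range(len(rect)))
        if len(ids) != len(rect):
            raise ValueError("one transect id per rectangle required")
        object.__setattr__(self, "transect_ids", tuple(str(t) for t in ids))
        # pairwise disjointness (rectangles are few; O(k^2) is fine)
        for i in range(len(rect)):
            for j in range(i + 1, len(rect)):
                a, b = rect[i], rect[j]
                if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                    raise ValueError("window rectangles overlap")

    @classmethod
    def study_design(
        cls,
        n_transects: int = 8,
        length_m: float = 6250.0,
        width_m: float = 50.0,
        spacing_m: float = 450.0,
    ) -> "TransectWindow":
        """Parallel east-west transects separated by ``spacing_m`` (edge to
        edge distance ``spacing_m - width_m``), the classic layout of
        large-area rainforest inventory designs."""
        rect = np.array(
            [
                [0.0, length_m, k * spacing_m, k * spacing_m + width_m]
                for k in range(n_transects)
            ]
        )
        return cls(rect)

    @property
    def n_rectangles(self) -> int:
        return len(self.rectangles)

    @property
    def total_area_m2(self) -> float:
        r = self.rectangles
        return float(np.sum((r[:, 1] - r[:, 0]) * (r[:, 3] - r[:, 2])))

    @property
    def total_area_ha(self) -> float:
        return self.total_area_m2 / 1e4

    def rect_index(self, points: np.ndarray) -> np.ndarray:
        """Index of the rectangle containing each point, -1 if outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.full(len(pts), -1, dtype=int)
        for k, (x0, x1, y0, y1) in enumerate(self.rectangles):
            inside = (
                (pts[:, 0] >= x0)
                & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0)
                & (pts[:, 1] <= y1)
            )
            idx[inside & (idx < 0)] = k
        return idx

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.rect_index(points) >= 0

    def set_covariance(self, dx, dy) -> np.ndarray:
        """Area of overlap between the window and itself shifted by (dx, dy).

        For disjoint rectangles separated by more than the shift this is the
        sum of per-rectangle terms (a - |dx|)+ (b - |dy|)+ ; it is the
        normaliser of the translation edge correction.
        """
        dx = np.abs(np.asarray(dx, dtype=float))
        dy = np.abs(np.asarray(dy, dtype=float))
        r = self.rectangles
        a = r[:, 1] - r[:, 0]
        b = r[:, 3] - r[:, 2]
        out = np.zeros(np.broadcast(dx, dy).shape, dtype=float)
        for ak, bk in zip(a, b):
            out += np.clip(ak - dx, 0.0, None) * np.clip(bk - dy, 0.0, None)
        return out

    def offset_of(self, transect_id: str) -> tuple[float, float]:
        """(x_min, y_min) of the rectangle of a transect."""
        try:
            k = self.transect_ids.index(str(transect_id))
        except ValueError:
            raise KeyError(f"unknown transect id {transect_id!r}") from None
        x0, _, y0, _ = self.rectangles[k]
        return float(x0), float(y0)

    def to_global(self, stems: pd.DataFrame) -> np.ndarray:
        """Map per-transect local (x, y) stem coordinates to the global frame."""
        pts = np.empty((len(stems), 2), dtype=float)
        for tid, sub in stems.groupby("transect_id", sort=False):
            x0, y0 = self.offset_of(tid)
            loc = stems.index.get_indexer(sub.index)
            pts[loc, 0] = sub["x"].to_numpy(dtype=float) + x0
            pts[loc, 1] = sub["y"].to_numpy(dtype=float) + y0
        return pts


@dataclass(frozen=True)
class DistanceBins:
    """Half-open distance classes (lo, hi] used by the correlograms.

    ``edges`` is a strictly increasing sequence of metres starting at 0;
    class ``c`` covers (edges[c], edges[c + 1]].  Pairs at distance exactly
    0 (self pairs, co-located stems) belong to no class.
    """

    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("need at least two bin edges")
        if edges[0] != 0.0:
            raise ValueError("bin edges must start at 0")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def study_default(cls) -> "DistanceBins":
        """Classes with upper bounds 100, 200, ..., 4000 m."""
        return cls(np.arange(0.0, 4100.0, 100.0))

    @classmethod
    def from_spec(cls, spec: str) -> "DistanceBins":
        """Parse 'step:stop' or 'start:stop:step' metre specs like '100:4000:100'."""
        parts = [float(p) for p in spec.split(":")]
        if len(parts) == 2:
            step, stop = parts
        elif len(parts) == 3:
            step, stop = parts[2], parts[1]
        else:
            raise ValueError(f"cannot parse bin spec {spec!r}")
        return cls(np.arange(0.0, stop + step / 2, step))

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Class index for each distance; -1 for distances outside all classes."""
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.edges, d, side="left") - 1
        idx[(d <= self.edges[0]) | (d > self.edges[-1])] = -1
        return idx


def validate_stems(
    stems: pd.DataFrame,
    window: TransectWindow | None = None,
    lookup: pd.DataFrame | None = None,
    dbh_threshold: float = DBH_THRESHOLD_CM,
) -> pd.DataFrame:
    """Check a stem table against the survey invariants.

    Raises :class:`StemDataError` on missing columns, dbh below the survey
    threshold, coordinates outside the declared window, or a guild
    inconsistent with the species lookup.
    """
    missing = [c for c in STEM_COLUMNS if c not in stems.columns]
    if missing:
        raise StemDataError(f"stem table missing columns: {missing}")
    if len(stems) == 0:
        return stems
    bad_guild = ~stems["guild"].isin(GUILDS)
    if bad_guild.any():
        raise StemDataError(
            f"unknown guild values: {sorted(stems.loc[bad_guild, 'guild'].unique())}"
        )
    if (stems["dbh"] < dbh_threshold).any():
        n = int((stems["dbh"] < dbh_threshold).sum())
        raise StemDataError(f"{n} stems below the {dbh_threshold} cm dbh threshold")
    if lookup is not None:
        mapping = lookup.set_index("species")["guild"]
        unknown = set(stems["species"]) - set(mapping.index)
        if unknown:
            raise StemDataError(f"species absent from lookup: {sorted(unknown)}")
        mismatch = stems["guild"].to_numpy() != mapping.loc[stems["species"]].to_numpy()
        if mismatch.any():
            raise StemDataError("guild column inconsistent with species lookup")
    if window is not None:
        pts = window.to_global(stems)
        outside = ~window.contains(pts)
        if outside.any():
            ids = stems.loc[outside, "tree_id"].tolist()[:5]
            raise StemDataError(f"stems outside the declared window (e.g. {ids})")
    return stems
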