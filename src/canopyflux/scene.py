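"""Forest plot scenes built from per-tree attribute tables.

Each segmented tree is reduced to a geometric crown primitive: a cone for
conifers and a semiellipsoid (upper half of an ellipsoid) for broadleaves.
A crown occupies z in [clear_bole_height, tree_height] with elliptical
footprint half-widths a (east-west) and b (north-south) and vertical extent
c = tree_height - clear_bole_height.  Only the upper/outer crown sheet is
modelled; trunks, base discs and interior foliage are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CONIFER",
    "BROADLEAF",
    "TreeRecord",
    "CrownPrimitive",
    "PlotScene",
    "load_tree_table",
    "scene_from_dataframe",
    "save_tree_table",
    "surface_height",
    "crown_volume",
    "scene_volume",
]

CONIFER = "conifer"
BROADLEAF = "broadleaf"

TABLE_COLUMNS = ["tree_id", "species_class", "center_x", "center_y",
                 "clear_bole_height", "tree_height", "half_width_ew",
                 "half_width_ns"]


@dataclass(frozen=True)
class TreeRecord:
    """One segmented tree: identity, species class and crown geometry (m)."""

    tree_id: str
    species_class: str
    center_x: float
    center_y: float
    clear_bole_height: float
    tree_height: float
    half_width_ew: float
    half_width_ns: float

    def __post_init__(self) -> None:
        if self.species_class not in (CONIFER, BROADLEAF):
            raise ValueError(
                f"tree {self.tree_id}: species_class must be "
                f"'{CONIFER}' or '{BROADLEAF}', got {self.species_class!r}")
        if self.clear_bole_height < 0:
            raise ValueError(f"tree {self.tree_id}: clear_bole_height < 0")
        if self.tree_height <= self.clear_bole_height:
            raise ValueError(
                f"tree {self.tree_id}: tree_height ({self.tree_height}) must "
                f"exceed clear_bole_height ({self.clear_bole_height})")
        if self.half_width_ew <= 0 or self.half_width_ns <= 0:
            raise ValueError(f"tree {self.tree_id}: crown half-widths must be > 0")


@dataclass(frozen=True)
class CrownPrimitive:
    """A tree crown as a cone (conifer) or semiellipsoid (broadleaf).

    ``shape`` is implied by the species class.  The cone has its apex at
    z = tree_height and base half-widths (a, b) at z = clear_bole_height;
    the semiellipsoid is the upper half of the ellipsoid centred at the
    clear bole height.
    """

    tree: TreeRecord

    @property
    def shape(self) -> str:
        return "cone" if self.tree.species_class == CONIFER else "semiellipsoid"

    @property
    def a(self) -> float:
        return self.tree.half_width_ew

    @property
    def b(self) -> float:
        return self.tree.half_width_ns

    @property
    def c(self) -> float:
        """Vertical crown extent: tree height minus clear bole height."""
        return self.tree.tree_height - self.tree.clear_bole_height

    @property
    def center(self) -> tuple[float, float, float]:
        return (self.tree.center_x, self.tree.center_y,
                self.tree.clear_bole_height)


def surface_height(primitive: CrownPrimitive, x: float, y: float) -> float | None:
    """Height of the crown's upper sheet above (x, y), or None outside it.

    Semiellipsoid: z = z_c + c*sqrt(1 - u); cone: z = tree_height - c*sqrt(u),
    where u = ((x-xc)/a)^2 + ((y-yc)/b)^2 is the squared elliptical radius.
    """
    xc, yc, zc = primitive.center
    u = ((x - xc) / primitive.a) ** 2 + ((y - yc) / primitive.b) ** 2
    if u > 1.0 + 1e-12:   # tolerate float fuzz exactly on the rim
        return None
    u = min(u, 1.0)
    if primitive.shape == "cone":
        return primitive.tree.tree_height - primitive.c * math.sqrt(u)
    return zc + primitive.c * math.sqrt(max(0.0, 1.0 - u))


def crown_volume(primitive: CrownPrimitive) -> float:
    """Closed-form crown volume: (1/3)pi*a*b*c cone, (2/3)pi*a*b*c semiellipsoid."""
    abc = primitive.a * primitive.b * primitive.c
    if primitive.shape == "cone":
        return math.pi * abc / 3.0
    return 2.0 * math.pi * abc / 3.0


@dataclass(frozen=True)
class PlotScene:
    """A rectangular plot and its crown primitives.

    ``bounds`` = (xmin, ymin, xmax, ymax) in plot-local meters.  Crown
    footprints may overlap each other and extend past the bounds; only the
    footprint *centers* are required to lie inside.
    """

    trees: tuple[CrownPrimitive, ...]
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 50.0, 50.0)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("plot bounds must span a positive area")
        for p in self.trees:
            if not (xmin <= p.tree.center_x <= xmax
                    and ymin <= p.tree.center_y <= ymax):
                raise ValueError(
                    f"tree {p.tree.tree_id} center outside plot bounds")

    @property
    def plot_area(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def counts_by_class(self) -> dict[str, int]:
        out = {CONIFER: 0, BROADLEAF: 0}
        for p in self.trees:
            out[p.tree.species_class] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{c: getattr(p.tree, c) for c in TABLE_COLUMNS}
                for p in self.trees]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def summary(self) -> pd.DataFrame:
        """Attribute-range summary (min/max/mean per numeric column)."""
        df = self.to_dataframe()
        num = df[TABLE_COLUMNS[2:]]
        return num.agg(["min", "max", "mean"])


def scene_from_records(records: Iterable[TreeRecord],
                       bounds: tuple[float, float, float, float] = (0, 0, 50, 50),
                       ) -> PlotScene:
    return PlotScene(trees=tuple(CrownPrimitive(r) for r in records),
                     bounds=tuple(float(v) for v in bounds))


def scene_from_dataframe(df: pd.DataFrame,
                         bounds: tuple[float, float, float, float] = (0, 0, 50, 50),
                         ) -> PlotScene:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(TreeRecord(
                tree_id=str(row["tree_id"]),
                species_class=str(row["species_class"]).strip().lower(),
                center_x=float(row["center_x"]),
                center_y=float(row["center_y"]),
                clear_bole_height=float(row["clear_bole_height"]),
                tree_height=float(row["tree_height"]),
                half_width_ew=float(row["half_width_ew"]),
                half_width_ns=float(row["half_width_ns"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"tree table row {idx}: {exc}") from exc
    return scene_from_records(records, bounds)


def load_tree_table(path: str | Path,
                    bounds: tuple[float, float, float, float] = (0, 0, 50, 50),
                    ) -> PlotScene:
    """Read a delimited tree-attribute table (CSV with header) into a scene."""
    df = pd.read_csv(path)
    return scene_from_dataframe(df, bounds)


def save_tree_table(scene: PlotScene, path: str | Path) -> None:
    scene.to_dataframe().to_csv(path, index=False)


def scene_volume(scene: PlotScene) -> float:
    """Total crown volume, m^3, summed per tree ignoring inter-crown overlap."""
    return sum(crown_volume(p) for p in scene.trees)
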