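"""Synthetic forest plots and deterministic toy fixtures.

Real per-tree layouts of the three study plots are not published; only the
per-plot attribute ranges (tree counts, height, crown width and clear-bole
ranges) are known.  The generator draws attributes uniformly and
independently within those ranges and places stems by minimum-spacing
rejection sampling, which is a convention, not an observed spatial pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import BROADLEAF, CONIFER, PlotScene, TreeRecord, scene_from_records

__all__ = ["AttributeRanges", "ScenarioSpec", "PLOT_SPECS", "generate_plot",
           "toy_fixture", "TOY_FIXTURES"]


@dataclass(frozen=True)
class AttributeRanges:
    """Uniform sampling ranges for one species class, meters.

    Half-width ranges are half the published full crown-width ranges.
    """

    tree_height: tuple[float, float]
    half_width_ew: tuple[float, float]
    half_width_ns: tuple[float, float]
    clear_bole_height: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in vars(self).items():
            if not 0 <= lo <= hi:
                raise ValueError(f"bad range for {name}: ({lo}, {hi})")
        if self.tree_height[0] <= self.clear_bole_height[1]:
            raise ValueError("height range must lie above the bole-height range")


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic plot.

    ``n_conifer``/``n_broadleaf`` split the stem count for mixed stands;
    ``minimum_stem_spacing`` (m) is enforced between stem centers by
    rejection sampling.
    """

    plot_kind: str
    n_conifer: int
    n_broadleaf: int
    conifer_ranges: AttributeRanges | None
    broadleaf_ranges: AttributeRanges | None
    plot_size: float = 50.0
    minimum_stem_spacing: float = 4.0

    @property
    def n_trees(self) -> int:
        return self.n_conifer + self.n_broadleaf


_CONIFER_PURE = AttributeRanges(tree_height=(15.4, 31.4),
                                half_width_ew=(1.1, 9.1),
                                half_width_ns=(1.25, 8.95),
                                clear_bole_height=(4.9, 10.6))
_BROADLEAF_PURE = AttributeRanges(tree_height=(9.7, 18.2),
                                  half_width_ew=(1.4, 6.3),
                                  half_width_ns=(1.65, 6.25),
                                  clear_bole_height=(2.1, 6.3))
_MIXED = AttributeRanges(tree_height=(10.3, 19.7),
                         half_width_ew=(1.05, 6.65),
                         half_width_ns=(1.0, 7.05),
                         clear_bole_height=(2.5, 7.1))

#: The three study-plot archetypes: pure conifer (60 cones), pure broadleaf
#: (60 semiellipsoids), and a mixed stand (33 conifers + 28 broadleaves).
PLOT_SPECS: dict[str, ScenarioSpec] = {
    "conifer": ScenarioSpec("conifer", 60, 0, _CONIFER_PURE, None,
                            minimum_stem_spacing=4.0),
    "broadleaf": ScenarioSpec("broadleaf", 0, 60, None, _BROADLEAF_PURE,
                              minimum_stem_spacing=5.0),
    "mixed": ScenarioSpec("mixed", 33, 28, _MIXED, _MIXED,
                          minimum_stem_spacing=5.0),
}


def _place_stems(n: int, size: float, spacing: float,
                 rng: np.random.Generator, max_tries: int = 20000) -> np.ndarray:
    """Minimum-spacing rejection placement of n stems in a size x size plot."""
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} stems with spacing {spacing} m in a "
                f"{size} x {size} m plot after {max_tries} draws")
        x, y = rng.uniform(0.0, size, size=2)
        tries += 1
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing ** 2
               for px, py in placed):
            placed.append((x, y))
    return np.asarray(placed)


def generate_plot(spec: ScenarioSpec | str, seed: int = 0) -> PlotScene:
    """Draw a random plot scene matching the given scenario spec.

    A string argument selects one of the ``PLOT_SPECS`` archetypes.
    Deterministic for a fixed (spec, seed).
    """
    if isinstance(spec, str):
        spec = PLOT_SPECS[spec]
    rng = np.random.default_rng(seed)
    if spec.n_trees == 0:
        return scene_from_records([], bounds=(0, 0, spec.plot_size, spec.plot_size))
    centers = _place_stems(spec.n_trees, spec.plot_size,
                           spec.minimum_stem_spacing, rng)
    records = []
    classes = ([CONIFER] * spec.n_conifer + [BROADLEAF] * spec.n_broadleaf)
    for i, (cls, (x, y)) in enumerate(zip(classes, centers)):
        ranges = (spec.conifer_ranges if cls == CONIFER
                  else spec.broadleaf_ranges)
        if ranges is None:
            raise ValueError(f"no attribute ranges for class {cls}")
        records.append(TreeRecord(
            tree_id=f"t{i:03d}",
            species_class=cls,
            center_x=float(x),
            center_y=float(y),
            clear_bole_height=float(rng.uniform(*ranges.clear_bole_height)),
            tree_height=float(rng.uniform(*ranges.tree_height)),
            half_width_ew=float(rng.uniform(*ranges.half_width_ew)),
            half_width_ns=float(rng.uniform(*ranges.half_width_ns)),
        ))
    return scene_from_records(records,
                              bounds=(0, 0, spec.plot_size, spec.plot_size))


def _tree(tree_id, cls, x, y, bole, height, a, b) -> TreeRecord:
    return TreeRecord(tree_id, cls, x, y, bole, height, a, b)


def toy_fixture(name: str) -> PlotScene:
    """Deterministic hand-specified scenes for oracle tests.

    - ``single_cone``: one conifer, a = b = 3 m, c = 10 m, bole 5 m.
    - ``single_ellipsoid``: one broadleaf, a = b = 3 m, c = 6 m, bole 4 m.
    - ``two_tree_shadow``: a tall conifer due south of a short one, so a low
      southern sun shades the rear tree.
    - ``flat_slab``: a near-degenerate broadleaf crown (c = 1 cm) that
      approximates a horizontal disc for conservation tests.
    """
    if name == "single_cone":
        recs = [_tree("cone0", CONIFER, 25.0, 25.0, 5.0, 15.0, 3.0, 3.0)]
    elif name == "single_ellipsoid":
        recs = [_tree("ell0", BROADLEAF, 25.0, 25.0, 4.0, 10.0, 3.0, 3.0)]
    elif name == "two_tree_shadow":
        # The front crown is wide and deep so its shadow envelope at a
        # ~34 deg southern sun fully covers the rear crown, whose clear bole
        # keeps its surface above the open space under the front crown.
        recs = [_tree("front", CONIFER, 25.0, 15.0, 3.0, 26.0, 8.0, 8.0),
                _tree("rear", CONIFER, 25.0, 24.0, 5.0, 11.0, 3.0, 3.0)]
    elif name == "flat_slab":
        recs = [_tree("slab0", BROADLEAF, 25.0, 25.0, 10.0, 10.01, 15.0, 15.0)]
    else:
        raise ValueError(f"unknown toy fixture {name!r}")
    return scene_from_records(recs, bounds=(0, 0, 50, 50))


TOY_FIXTURES = ("single_cone", "single_ellipsoid", "two_tree_shadow",
                "flat_slab")
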