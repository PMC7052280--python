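"""Augmented 2D field-trial design, plot polygons and the virtual grid.

The design emulated here is the classic augmented layout used in wheat
phenotyping trials: a small set of check varieties is replicated in complete
blocks within each replicate, and a large set of unreplicated test genotypes
is augmented onto the remaining cells.  The default configuration is two
replicates of 21 rows x 18 ranges (378 plots each), with 3 checks distributed
in nine complete 7x6 blocks so that every row and every range of a replicate
contains at least one check plot (27 check plots per replicate).

Both replicates are embedded in a single "virtual grid" of rows 1-74 and
ranges 1-18, with an empty gap of rows between them, which is the coordinate
system the spatial model operates on.

Coordinate conventions: planar metric coordinates with x along the range
direction and y along the row direction; origin at the corner of the first
replicate; polygons are closed counter-clockwise rings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Polygon, mapping

from .errors import ConstraintError, DimensionError, LayoutError

# Default geometry of the emulated trial: plot cells of 2.7 m x 1.5 m pitch
# containing a 1.7 m x 1.0 m sown plot (the pitch includes inter-plot paths).
DEFAULT_CELL_PITCH = (2.7, 1.5)  # (length along x/range, width along y/row), m
DEFAULT_SOWN_SIZE = (1.7, 1.0)  # sown plot dimensions, m

MAX_RANDOMIZATION_RETRIES = 10_000


@dataclass
class PlotRecord:
    """One plot of the trial.

    ``row``/``range`` are replicate-local 1-based coordinates; ``virtual_row``
    and ``virtual_range`` place the plot on the shared virtual grid (filled by
    :func:`build_virtual_grid`).  ``genotype_id`` is ``None`` for unused filler
    cells in degenerate designs.
    """

    plot_id: str
    genotype_id: str | None
    is_check: bool
    replicate: int
    row: int
    range: int
    virtual_row: int | None = None
    virtual_range: int | None = None
    polygon: Polygon | None = None

    @property
    def is_filler(self) -> bool:
        return self.genotype_id is None


@dataclass
class TrialDesign:
    """An augmented 2D design over one or more replicates."""

    plots: list[PlotRecord]
    n_genotypes: int
    check_ids: tuple[str, ...]
    rep_shape: tuple[int, int]  # (rows, ranges) per replicate
    origin: tuple[float, float] = (0.0, 0.0)
    cell_pitch: tuple[float, float] = DEFAULT_CELL_PITCH
    sown_size: tuple[float, float] = DEFAULT_SOWN_SIZE
    virtual_shape: tuple[int, int] | None = None  # (rows, ranges) incl. gap
    rep_row_spans: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def replicates(self) -> list[int]:
        return sorted({p.replicate for p in self.plots})

    def plots_of(self, replicate: int) -> list[PlotRecord]:
        return [p for p in self.plots if p.replicate == replicate]

    def to_frame(self) -> pd.DataFrame:
        """Design table with one row per plot (fixed column order)."""
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "genotype_id": [p.genotype_id for p in self.plots],
                "is_check": [p.is_check for p in self.plots],
                "replicate": [p.replicate for p in self.plots],
                "row": [p.row for p in self.plots],
                "range": [p.range for p in self.plots],
                "virtual_row": [p.virtual_row for p in self.plots],
                "virtual_range": [p.virtual_range for p in self.plots],
            }
        )

    def to_geojson(self) -> dict:
        """GeoJSON FeatureCollection of plot polygons with design properties."""
        features = []
        for p in self.plots:
            if p.polygon is None:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(p.polygon),
                    "properties": {
                        "plot_id": p.plot_id,
                        "genotype_id": p.genotype_id,
                        "is_check": p.is_check,
                        "replicate": p.replicate,
                        "row": p.row,
                        "range": p.range,
                        "virtual_row": p.virtual_row,
                        "virtual_range": p.virtual_range,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def _covering_subsets(
    rng: np.random.Generator, n_blocks: int, n_per_block: int, domain: int, cover: bool
) -> list[np.ndarray]:
    """Draw ``n_blocks`` subsets of ``n_per_block`` distinct values in
    ``range(domain)``, redrawn until their union covers the domain (when
    ``cover``).  Uniform over all covering configurations."""
    for _ in range(MAX_RANDOMIZATION_RETRIES):
        subsets = [rng.choice(domain, size=n_per_block, replace=False) for _ in range(n_blocks)]
        if not cover or len({int(v) for s in subsets for v in s}) == domain:
            return subsets
    raise ConstraintError(
        "row/range check-coverage constraint not satisfied within "
        f"{MAX_RANDOMIZATION_RETRIES} randomization attempts"
    )


def _randomize_checks(
    rng: np.random.Generator,
    rep_shape: tuple[int, int],
    block_shape: tuple[int, int],
    n_checks: int,
    require_coverage: bool,
) -> list[tuple[int, int]]:
    """Place ``n_checks`` checks in every complete block.

    Within each block the checks occupy distinct block-local rows and distinct
    block-local ranges (one cell per row/range stratum), and placements are
    redrawn until every replicate row and range holds at least one check.  The
    row constraint couples only the blocks of one horizontal band and the
    range constraint only those of one vertical band, so rejection is applied
    per band, which leaves the distribution uniform over valid placements.
    """
    n_rows, n_rngs = rep_shape
    b_rows, b_rngs = block_shape
    nb_r, nb_c = n_rows // b_rows, n_rngs // b_rngs
    cover_rows = require_coverage and nb_c * n_checks >= b_rows
    cover_rngs = require_coverage and nb_r * n_checks >= b_rngs
    # row-band bi: one row-subset per block in the band (indexed by bj)
    row_sets = [
        _covering_subsets(rng, nb_c, n_checks, b_rows, cover_rows) for _ in range(nb_r)
    ]
    col_sets = [
        _covering_subsets(rng, nb_r, n_checks, b_rngs, cover_rngs) for _ in range(nb_c)
    ]
    cells = []
    for bi in range(nb_r):
        for bj in range(nb_c):
            rows = row_sets[bi][bj]
            cols = rng.permuted(col_sets[bj][bi])
            for r, c in zip(rows, cols):
                cells.append((bi * b_rows + int(r) + 1, bj * b_rngs + int(c) + 1))
    return cells


def generate_design(
    n_test: int = 351,
    check_ids: Sequence[str] = ("CH_CLARO", "SURETTA", "CH_NARA"),
    rep_shape: tuple[int, int] = (21, 18),
    check_block_shape: tuple[int, int] = (7, 6),
    n_replicates: int = 2,
    seed: int = 0,
    cell_pitch: tuple[float, float] = DEFAULT_CELL_PITCH,
    sown_size: tuple[float, float] = DEFAULT_SOWN_SIZE,
) -> TrialDesign:
    """Generate a randomized augmented 2D design.

    Checks are placed once per complete block (distinct block-local rows and
    ranges), re-randomized until every row and every range of the replicate
    contains at least one check whenever the check count makes that possible.
    Test genotypes are then augmented onto the remaining cells in random
    order; any surplus cells are flagged as filler (``genotype_id = None``).

    Deterministic for a fixed ``seed``.
    """
    n_rows, n_rngs = rep_shape
    b_rows, b_rngs = check_block_shape
    if n_rows % b_rows or n_rngs % b_rngs:
        raise DimensionError(
            f"check block shape {check_block_shape} does not tile replicate {rep_shape}"
        )
    check_ids = tuple(dict.fromkeys(check_ids))
    n_checks = len(check_ids)
    n_blocks = (n_rows // b_rows) * (n_rngs // b_rngs)
    n_check_plots = n_checks * n_blocks
    n_cells = n_rows * n_rngs
    if n_check_plots + n_test > n_cells:
        raise DimensionError(
            f"{n_test} test genotypes + {n_check_plots} check plots exceed "
            f"{n_cells} cells per replicate"
        )
    # Coverage of all rows/ranges by checks is only enforceable when there are
    # at least as many check plots as rows and as ranges.
    require_coverage = n_check_plots >= max(n_rows, n_rngs)

    test_ids = [f"G{idx:03d}" for idx in range(1, n_test + 1)]
    rng = np.random.default_rng(seed)
    plots: list[PlotRecord] = []
    for rep in range(1, n_replicates + 1):
        check_cells = _randomize_checks(
            rng, rep_shape, check_block_shape, n_checks, require_coverage
        )
        # one check id per block in randomized order, one block at a time
        cell_geno: dict[tuple[int, int], tuple[str, bool]] = {}
        for b in range(n_blocks):
            order = rng.permutation(n_checks)
            for k, cell in zip(order, check_cells[b * n_checks : (b + 1) * n_checks]):
                cell_geno[cell] = (check_ids[int(k)], True)
        free = [
            (r, c)
            for r in range(1, n_rows + 1)
            for c in range(1, n_rngs + 1)
            if (r, c) not in cell_geno
        ]
        order = rng.permutation(len(free))
        for k, gid in zip(order, test_ids):
            cell_geno[free[int(k)]] = (gid, False)
        for r in range(1, n_rows + 1):
            for c in range(1, n_rngs + 1):
                gid, is_check = cell_geno.get((r, c), (None, False))
                plots.append(
                    PlotRecord(
                        plot_id=f"{rep}_{r:02d}_{c:02d}",
                        genotype_id=gid,
                        is_check=is_check,
                        replicate=rep,
                        row=r,
                        range=c,
                    )
                )
    return TrialDesign(
        plots=plots,
        n_genotypes=n_test + n_checks,
        check_ids=check_ids,
        rep_shape=rep_shape,
        cell_pitch=cell_pitch,
        sown_size=sown_size,
    )


def build_virtual_grid(
    design: TrialDesign,
    rep1_rows: tuple[int, int] = (1, 21),
    rep2_rows: tuple[int, int] = (54, 74),
) -> TrialDesign:
    """Map replicate-local (row, range) onto the shared virtual grid.

    ``rep1_rows``/``rep2_rows`` are the inclusive virtual-row spans of the two
    replicates; the unassigned rows in between form the separating gap (the
    parcel between the two field lots).  Returns the same design with
    ``virtual_row``/``virtual_range`` filled in.
    """
    spans = {1: rep1_rows, 2: rep2_rows}
    n_rows = design.rep_shape[0]
    reps = design.replicates
    used: set[int] = set()
    for rep in reps:
        lo, hi = spans[rep]
        if hi - lo + 1 != n_rows:
            raise LayoutError(
                f"replicate {rep} span {spans[rep]} does not hold {n_rows} rows"
            )
        if lo < 1:
            raise LayoutError(f"replicate {rep} span {spans[rep]} below row 1")
        rows = set(range(lo, hi + 1))
        if rows & used:
            raise LayoutError("replicate virtual-row spans overlap")
        used |= rows
    for p in design.plots:
        lo, _ = spans[p.replicate]
        p.virtual_row = lo + p.row - 1
        p.virtual_range = p.range
    design.virtual_shape = (max(used), design.rep_shape[1])
    design.rep_row_spans = {rep: spans[rep] for rep in reps}
    return design


def separating_rows(design: TrialDesign) -> int:
    """Number of empty virtual rows between replicates 1 and 2."""
    if not design.rep_row_spans:
        raise LayoutError("virtual grid not built")
    s1, s2 = design.rep_row_spans[1], design.rep_row_spans[2]
    first, second = sorted([s1, s2])
    return second[0] - first[1] - 1


def virtual_to_local(design: TrialDesign, virtual_row: int, virtual_range: int):
    """Invert the virtual mapping: (replicate, local row, range) of a cell."""
    for rep, (lo, hi) in design.rep_row_spans.items():
        if lo <= virtual_row <= hi:
            return rep, virtual_row - lo + 1, virtual_range
    raise LayoutError(f"virtual row {virtual_row} lies in the separating gap")


def plot_polygons(
    design: TrialDesign,
    origin: tuple[float, float] = (0.0, 0.0),
    pitch: tuple[float, float] | None = None,
    heading: float = 0.0,
) -> list[Polygon]:
    """Attach a rectangular cell polygon to every plot.

    Plots sit on a regular grid in the virtual-coordinate plane: x advances
    with the range index (cell length), y with the virtual row index (cell
    width).  ``heading`` rotates the whole layout counter-clockwise about
    ``origin`` (degrees).  Rings are closed and counter-clockwise; adjacent
    plots share edges but no interior.
    """
    if pitch is None:
        pitch = design.cell_pitch
    px, py = pitch
    if px <= 0 or py <= 0:
        raise DimensionError(f"cell pitch must be positive, got {pitch}")
    design.cell_pitch = (px, py)
    ox, oy = origin
    design.origin = (ox, oy)
    polys = []
    for p in design.plots:
        vr = p.virtual_row if p.virtual_row is not None else p.row
        vc = p.virtual_range if p.virtual_range is not None else p.range
        x0 = ox + (vc - 1) * px
        y0 = oy + (vr - 1) * py
        poly = Polygon(
            [(x0, y0), (x0 + px, y0), (x0 + px, y0 + py), (x0, y0 + py), (x0, y0)]
        )
        if heading != 0.0:
            poly = affinity.rotate(poly, heading, origin=(ox, oy))
        p.polygon = poly
        polys.append(poly)
    return polys
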