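"""Tile-grid planning, pairwise registration, and blended mosaic assembly.

Stage-scanned acquisitions cover large samples with a lattice of overlapping
tiles (typically 50% overlap).  This module plans such lattices, refines tile
positions by integer-pixel normalized cross-correlation on the overlap of
neighbouring tiles, resolves global positions by chaining measured shifts
along a maximum-confidence spanning tree, and assembles the tiles into one
image with linear-ramp feathering.

Registration is translation-only with integer shifts, which matches a
stage-scanned lattice; there is no rotation, scale, or subpixel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MosaicPlan",
    "PairRegistration",
    "TileOffsets",
    "PlanningError",
    "RegistrationError",
    "plan_grid",
    "register_pair",
    "register_grid",
    "resolve_positions",
    "assemble_mosaic",
]


class PlanningError(ValueError):
    """Raised for an inconsistent grid/tile/step specification."""


class RegistrationError(ValueError):
    """Raised for unusable registration inputs (tiny overlap, bad shapes)."""


#: Minimum admissible overlap, in pixels, along the overlap dimension.
MIN_OVERLAP_PX = 16


@dataclass(frozen=True)
class MosaicPlan:
    """A regular lattice of tiles and the canvas it spans."""

    grid_rows: int
    grid_cols: int
    tile_px: int
    step_px: int
    positions: np.ndarray = field(repr=False)  # (n_tiles, 2) of (y, x)
    canvas_px: tuple[int, int] = (0, 0)

    @property
    def n_tiles(self) -> int:
        return self.grid_rows * self.grid_cols

    def tile_index(self, grid_row: int, grid_col: int) -> int:
        return grid_row * self.grid_cols + grid_col


@dataclass
class PairRegistration:
    """Measured relative shift between two neighbouring tiles."""

    shift: tuple[int, int]  # (dy, dx) of tile_b relative to tile_a
    confidence: float  # normalized cross-correlation at the optimum
    failed: bool = False  # True when the nominal shift was retained


@dataclass
class TileOffsets:
    """Pairwise measurements and the resolved global tile positions."""

    pairs: dict[tuple[int, int], PairRegistration]
    positions: np.ndarray  # (n_tiles, 2) of (y, x), anchor at (0, 0)


def plan_grid(grid: tuple[int, int], tile_px: int, step_px: int) -> MosaicPlan:
    """Plan a ``rows x cols`` lattice of ``tile_px`` tiles at pitch ``step_px``.

    The canvas extent per axis is ``tile_px + (n - 1) * step_px``.  A 3-tile
    side of 1440-px tiles at step 744 px spans 2928 px.
    """
    g_rows, g_cols = grid
    if g_rows < 1 or g_cols < 1:
        raise PlanningError("grid must be at least 1 x 1")
    if not 0 < step_px <= tile_px:
        raise PlanningError(
            "need 0 < step_px <= tile_px (a larger step leaves gaps)"
        )
    positions = np.array(
        [
            (r * step_px, c * step_px)
            for r in range(g_rows)
            for c in range(g_cols)
        ],
        dtype=np.int64,
    ).reshape(g_rows * g_cols, 2)
    canvas = (
        tile_px + (g_rows - 1) * step_px,
        tile_px + (g_cols - 1) * step_px,
    )
    return MosaicPlan(
        grid_rows=g_rows,
        grid_cols=g_cols,
        tile_px=tile_px,
        step_px=step_px,
        positions=positions,
        canvas_px=canvas,
    )


def _overlap_slices(
    shape_a: tuple[int, int], shape_b: tuple[int, int], shift: tuple[int, int]
) -> tuple[tuple[slice, slice], tuple[slice, slice]] | None:
    """Index slices of the overlap of B placed at ``shift`` relative to A."""
    dy, dx = shift
    ay0, ax0 = max(0, dy), max(0, dx)
    ay1 = min(shape_a[0], dy + shape_b[0])
    ax1 = min(shape_a[1], dx + shape_b[1])
    if ay1 <= ay0 or ax1 <= ax0:
        return None
    by0, bx0 = ay0 - dy, ax0 - dx
    return (
        (slice(ay0, ay1), slice(ax0, ax1)),
        (slice(by0, by0 + (ay1 - ay0)), slice(bx0, bx0 + (ax1 - ax0))),
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return None
    return float((a * b).sum() / denom)


def register_pair(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_shift: tuple[int, int],
    search_radius: int = 5,
) -> PairRegistration:
    """Refine the shift of ``tile_b`` relative to ``tile_a``.

    Exhaustively evaluates every integer shift within ``search_radius`` of the
    nominal one and returns the shift maximizing the normalized
    cross-correlation of the overlap, with the correlation as confidence.
    If every candidate overlap is smaller than :data:`MIN_OVERLAP_PX` or has
    zero variance, the nominal shift is retained and ``failed`` is set.
    """
    tile_a = np.asarray(tile_a)
    tile_b = np.asarray(tile_b)
    if tile_a.ndim != 2 or tile_b.ndim != 2:
        raise RegistrationError("tiles must be 2-D images")
    slices = _overlap_slices(tile_a.shape, tile_b.shape, nominal_shift)
    if slices is None or min(
        slices[0][0].stop - slices[0][0].start,
        slices[0][1].stop - slices[0][1].start,
    ) < MIN_OVERLAP_PX:
        raise RegistrationError(
            f"overlap at the nominal shift is below {MIN_OVERLAP_PX} px"
        )

    best_shift, best_conf = None, -np.inf
    dy0, dx0 = nominal_shift
    for dy in range(dy0 - search_radius, dy0 + search_radius + 1):
        for dx in range(dx0 - search_radius, dx0 + search_radius + 1):
            sl = _overlap_slices(tile_a.shape, tile_b.shape, (dy, dx))
            if sl is None:
                continue
            (asl, bsl) = sl
            if min(
                asl[0].stop - asl[0].start, asl[1].stop - asl[1].start
            ) < MIN_OVERLAP_PX:
                continue
            conf = _ncc(tile_a[asl], tile_b[bsl])
            if conf is not None and conf > best_conf:
                best_shift, best_conf = (dy, dx), conf
    if best_shift is None:
        return PairRegistration(
            shift=tuple(nominal_shift), confidence=0.0, failed=True
        )
    return PairRegistration(shift=best_shift, confidence=best_conf)


def register_grid(
    tiles: list[np.ndarray], plan: MosaicPlan, search_radius: int = 5
) -> dict[tuple[int, int], PairRegistration]:
    """Register every horizontally and vertically adjacent tile pair."""
    pairs: dict[tuple[int, int], PairRegistration] = {}
    for r in range(plan.grid_rows):
        for c in range(plan.grid_cols):
            i = plan.tile_index(r, c)
            for rr, cc in ((r, c + 1), (r + 1, c)):
                if rr >= plan.grid_rows or cc >= plan.grid_cols:
                    continue
                j = plan.tile_index(rr, cc)
                nominal = (
                    int(plan.positions[j, 0] - plan.positions[i, 0]),
                    int(plan.positions[j, 1] - plan.positions[i, 1]),
                )
                pairs[(i, j)] = register_pair(
                    tiles[i], tiles[j], nominal, search_radius
                )
    return pairs


def resolve_positions(
    plan: MosaicPlan, pairs: dict[tuple[int, int], PairRegistration]
) -> TileOffsets:
    """Resolve global tile positions from pairwise shifts.

    Builds the tile adjacency graph weighted by registration confidence,
    extracts its maximum-confidence spanning tree, and chains measured shifts
    outward from the top-left anchor tile, which is fixed at the origin.
    Deterministic for a given set of measurements.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(plan.n_tiles))
    for (i, j), reg in pairs.items():
        graph.add_edge(i, j, weight=reg.confidence, reg=reg, src=i)
    if plan.n_tiles > 1 and not nx.is_connected(graph):
        raise RegistrationError("pairwise measurements do not connect the grid")
    tree = nx.maximum_spanning_tree(graph, weight="weight")
    positions = np.zeros((plan.n_tiles, 2), dtype=np.int64)
    for parent, child in nx.bfs_edges(tree, source=0):
        data = tree.edges[parent, child]
        dy, dx = data["reg"].shift
        if data["src"] == parent:
            positions[child] = positions[parent] + (dy, dx)
        else:
            positions[child] = positions[parent] - np.array((dy, dx))
    return TileOffsets(pairs=pairs, positions=positions)


def _feather_weights(shape: tuple[int, int]) -> np.ndarray:
    # Separable linear ramp rising from 1 at the tile border; integer-valued
    # so that blending equal-valued overlaps is exact in floating point.
    h, w = shape
    wy = np.minimum(np.arange(1, h + 1), np.arange(h, 0, -1)).astype(np.float64)
    wx = np.minimum(np.arange(1, w + 1), np.arange(w, 0, -1)).astype(np.float64)
    return np.outer(wy, wx)


def assemble_mosaic(
    tiles: list[np.ndarray],
    positions: np.ndarray | TileOffsets,
    blend: str = "feather",
) -> np.ndarray:
    """Assemble tiles at integer positions into one blended image.

    Overlapping pixels are combined by weights normalised to sum to one:
    ``"feather"`` uses a linear ramp from the tile edges, ``"mean"`` uniform
    weights.  The canvas is the bounding box of the placed tiles.
    """
    if len(tiles) == 0:
        raise ValueError("no tiles to assemble")
    if blend not in ("feather", "mean"):
        raise ValueError(f"unknown blend mode: {blend!r}")
    if isinstance(positions, TileOffsets):
        positions = positions.positions
    positions = np.asarray(positions, dtype=np.int64)
    if positions.shape != (len(tiles), 2):
        raise ValueError("positions must be (n_tiles, 2)")

    origin = positions.min(axis=0)
    shifted = positions - origin
    extents = shifted + np.array([t.shape for t in tiles])
    canvas_shape = tuple(extents.max(axis=0))
    acc = np.zeros(canvas_shape)
    wacc = np.zeros(canvas_shape)
    for tile, (y, x) in zip(tiles, shifted):
        tile = np.asarray(tile, dtype=np.float64)
        w = (
            _feather_weights(tile.shape)
            if blend == "feather"
            else np.ones(tile.shape)
        )
        acc[y : y + tile.shape[0], x : x + tile.shape[1]] += w * tile
        wacc[y : y + tile.shape[0], x : x + tile.shape[1]] += w
    covered = wacc > 0
    mosaic = np.zeros(canvas_shape)
    mosaic[covered] = acc[covered] / wacc[covered]
    return mosaic
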