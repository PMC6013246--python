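"""Spatial statistics of nuclear patterns.

These operate identically on measured, synthetic and simulated
configurations: nearest-neighbour distances with a random-placement
baseline, single-file / double-file (SF/DF) classification from the
histogram of relative x-positions, pooled positional histograms, zigzag
auto-/cross-correlations along the long axis, and the oriented aspect
ratio of fitted nuclear ellipses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dynamics import CellGeometry

#: Number of equal bins of relative x-position used for SF/DF classification.
N_CLASS_BINS = 7

#: Fraction of all nuclei the peak bin(s) must contain.
PEAK_FRACTION = 0.6

#: Default NND histogram bin edges (um).
NND_BIN_EDGES = np.arange(0.0, 151.0, 10.0)


# ---------------------------------------------------------------------------
# nearest-neighbour distances
# ---------------------------------------------------------------------------

def nearest_neighbor_distances(positions) -> np.ndarray:
    """Per-nucleus Euclidean distance to the closest other nucleus (um)."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least two nuclei for nearest-neighbour distances")
    D = squareform(pdist(pos))
    np.fill_diagonal(D, np.inf)
    return D.min(axis=1)


@dataclass
class NNDBaseline:
    """Monte-Carlo NND statistics for independently uniform nuclei."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    mean_nnd: float
    sd_nnd: float
    n_realizations: int


def random_nnd_baseline(
    geom: CellGeometry,
    n_real: int = 1000,
    seed=0,
    bin_edges: np.ndarray = NND_BIN_EDGES,
) -> NNDBaseline:
    """Null model: x and y i.i.d. uniform over the full rectangle.

    Returns per-bin mean and SD of the NND histogram across realizations,
    plus mean and SD of the per-realization mean NND.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    if geom.n_nuclei < 2:
        raise ValueError("need at least two nuclei")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_real, len(bin_edges) - 1))
    means = np.empty(n_real)
    for k in range(n_real):
        pos = np.column_stack([
            rng.uniform(-geom.half_width, geom.half_width, geom.n_nuclei),
            rng.uniform(-geom.half_length, geom.half_length, geom.n_nuclei),
        ])
        nnd = nearest_neighbor_distances(pos)
        counts[k] = np.histogram(nnd, bins=bin_edges)[0]
        means[k] = nnd.mean()
    return NNDBaseline(
        bin_edges=np.asarray(bin_edges, dtype=float),
        mean_counts=counts.mean(axis=0),
        sd_counts=counts.std(axis=0, ddof=1) if n_real > 1 else np.zeros(counts.shape[1]),
        mean_nnd=float(means.mean()),
        sd_nnd=float(means.std(ddof=1)) if n_real > 1 else 0.0,
        n_realizations=n_real,
    )


# ---------------------------------------------------------------------------
# SF / DF classification
# ---------------------------------------------------------------------------

@dataclass
class PatternLabel:
    """SF/DF/neither label with the 7-bin x-position histogram behind it."""

    label: Literal["SF", "DF", "neither"]
    histogram: np.ndarray
    peak_bins: tuple


def classify_pattern(positions, geom: CellGeometry) -> PatternLabel:
    """Classify a configuration as single file, double file or neither.

    The relative x-positions x/b are histogrammed into 7 equal bins over
    [-1, 1].  SF: the single highest bin holds at least 60% of the nuclei.
    DF: the two highest bins are non-adjacent, jointly hold at least 60%,
    and their counts differ by less than 50% (|n1-n2|/max(n1,n2) < 0.5).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least two nuclei to classify a pattern")
    rel = pos[:, 0] / geom.half_width
    counts, _ = np.histogram(np.clip(rel, -1.0, 1.0), bins=N_CLASS_BINS, range=(-1.0, 1.0))
    n = pos.shape[0]
    order = np.argsort(counts, kind="stable")[::-1]
    top, second = int(order[0]), int(order[1])
    if counts[top] >= PEAK_FRACTION * n and counts[top] > counts[second]:
        return PatternLabel("SF", counts, (top,))
    n1, n2 = int(counts[top]), int(counts[second])
    if (
        abs(top - second) > 1
        and n1 + n2 >= PEAK_FRACTION * n
        and n2 > 0
        and (n1 - n2) / max(n1, n2) < 0.5
    ):
        return PatternLabel("DF", counts, tuple(sorted((top, second))))
    return PatternLabel("neither", counts, ())


# ---------------------------------------------------------------------------
# positional histograms and x-spread
# ---------------------------------------------------------------------------

@dataclass
class PositionalHistograms:
    x_centers: np.ndarray
    x_density: np.ndarray
    y_centers: np.ndarray
    y_density: np.ndarray
    n_nuclei: int


def positional_histograms(cells: Iterable[tuple], n_bins: int = 10) -> PositionalHistograms:
    """Pooled histograms of relative positions x/b and y/l over [-1, 1].

    ``cells`` is an iterable of (CellGeometry, positions).  Densities are
    fractions of all pooled nuclei per bin.
    """
    xs, ys = [], []
    for geom, pos in cells:
        pos = np.asarray(pos, dtype=float)
        xs.append(pos[:, 0] / geom.half_width)
        ys.append(pos[:, 1] / geom.half_length)
    if not xs:
        raise ValueError("need at least one cell")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    cx, _ = np.histogram(x, bins=n_bins, range=(-1, 1))
    cy, _ = np.histogram(y, bins=n_bins, range=(-1, 1))
    edges = np.linspace(-1, 1, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PositionalHistograms(centers, cx / len(x), centers, cy / len(y), len(x))


def mean_abs_x(positions, geom: CellGeometry | None = None) -> float:
    """Average distance of the nuclei from the cell midline (um)."""
    pos = np.asarray(positions, dtype=float)
    return float(np.abs(pos[:, 0]).mean())


# ---------------------------------------------------------------------------
# zigzag correlations along the long axis
# ---------------------------------------------------------------------------

#: Bin spacing of correlation histograms in normalised spacing units.
CORR_BIN = 0.25

#: Fraction of the cell height near each pole whose nuclei are discarded.
POLE_TRIM_FRACTION = 0.1


@dataclass
class CorrelationResult:
    kind: Literal["auto_SF", "auto_DF_row", "cross_DF"]
    bin_centers: np.ndarray
    counts: np.ndarray
    n_cells: int

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


def _corr_bins(max_offset: float = 3.0):
    centers = np.arange(-max_offset, max_offset + CORR_BIN / 2, CORR_BIN)
    edges = np.concatenate([centers - CORR_BIN / 2, [centers[-1] + CORR_BIN / 2]])
    return centers, edges


def _trim_poles(pos: np.ndarray, geom: CellGeometry) -> np.ndarray:
    cut = geom.half_length - POLE_TRIM_FRACTION * 2.0 * geom.half_length
    return pos[np.abs(pos[:, 1]) <= cut]


def _shift_middle(y: np.ndarray) -> np.ndarray:
    # middle-most nucleus (median rank) sits at 0
    order = np.argsort(y)
    mid = y[order[(len(y) - 1) // 2]]
    return y - mid


def zigzag_correlations(
    cells: Sequence[tuple],
    labels: Optional[Sequence[str]] = None,
    max_offset: float = 3.0,
) -> dict:
    """Auto- and cross-correlation histograms of y-positions along the cell.

    Nuclei within 10% of the cell height of either pole are discarded.
    y-positions are rescaled so the mean spacing *within a file* is 1 (for
    DF cells a single scale, the mean of the two per-row unit-spacing
    factors, is applied to both rows so their relative alignment survives),
    then shifted so the middle-most nucleus sits at 0 and pooled over cells.

    Histograms (bin 0.25): pairwise offsets within the single file
    (``auto_SF``), within each DF row (``auto_DF_row``), and between one DF
    row and the midpoints of consecutive nuclei of the other row
    (``cross_DF``) — the signature of the zigzag: a perfect zigzag peaks at
    integer offsets, perfectly paired rows at half-integers.
    """
    if labels is None:
        labels = [classify_pattern(pos, geom).label for geom, pos in cells]
    centers, edges = _corr_bins(max_offset)
    pooled = {k: [] for k in ("auto_SF", "auto_DF_row", "cross_DF")}
    n_cells = {k: 0 for k in pooled}

    for (geom, pos), label in zip(cells, labels):
        pos = _trim_poles(np.asarray(pos, dtype=float), geom)
        if label == "SF":
            y = np.sort(pos[:, 1])
            if len(y) < 2 or y[-1] == y[0]:
                continue
            y = _shift_middle(y * (len(y) - 1) / (y[-1] - y[0]))
            diffs = (y[:, None] - y[None, :])[~np.eye(len(y), dtype=bool)]
            pooled["auto_SF"].append(diffs)
            n_cells["auto_SF"] += 1
        elif label == "DF":
            left = np.sort(pos[pos[:, 0] < 0, 1])
            right = np.sort(pos[pos[:, 0] >= 0, 1])
            if len(left) < 2 or len(right) < 2:
                continue
            scale = 0.5 * (
                (len(left) - 1) / (left[-1] - left[0])
                + (len(right) - 1) / (right[-1] - right[0])
            )
            ally = np.concatenate([left, right]) * scale
            mid_val = np.sort(ally)[(len(ally) - 1) // 2]
            left = left * scale - mid_val
            right = right * scale - mid_val
            for row in (left, right):
                diffs = (row[:, None] - row[None, :])[~np.eye(len(row), dtype=bool)]
                pooled["auto_DF_row"].append(diffs)
            mid = 0.5 * (right[:-1] + right[1:])
            pooled["cross_DF"].append((left[:, None] - mid[None, :]).ravel())
            n_cells["auto_DF_row"] += 1
            n_cells["cross_DF"] += 1

    out = {}
    for kind in pooled:
        if pooled[kind]:
            counts = np.histogram(np.concatenate(pooled[kind]), bins=edges)[0]
        else:
            counts = np.zeros(len(centers), dtype=int)
        out[kind] = CorrelationResult(kind, centers, counts, n_cells[kind])
    return out


# ---------------------------------------------------------------------------
# nuclear ellipses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NuclearEllipse:
    """Fitted nuclear outline: centroid (um), axis lengths (um), angle phi.

    ``orientation`` is the major-axis angle in [0, pi), measured from the
    x-axis (the cell's short axis); pi/2 means the nucleus is elongated
    along the cell's long axis.
    """

    centroid: tuple
    major: float
    minor: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.major >= self.minor > 0):
            raise ValueError("require major >= minor > 0")
        if not (0 <= self.orientation < math.pi):
            raise ValueError("orientation must lie in [0, pi)")


def aspect_ratio_from_ellipse(e: NuclearEllipse) -> float:
    """Oriented aspect ratio: > 1 along the cell axis, < 1 across it.

    l_M/l_m when the major axis lies within pi/4 of the long (y) axis,
    otherwise the reciprocal.
    """
    if abs(e.orientation - math.pi / 2) <= math.pi / 4:
        return e.major / e.minor
    return e.minor / e.major
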