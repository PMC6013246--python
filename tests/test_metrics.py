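"""Pattern statistics: NND, SF/DF classification, histograms, correlations."""

import numpy as np
import pytest

from myopos import (
    CellGeometry,
    NuclearEllipse,
    aspect_ratio_from_ellipse,
    classify_pattern,
    mean_abs_x,
    nearest_neighbor_distances,
    positional_histograms,
    random_nnd_baseline,
    zigzag_correlations,
)


def _cfg(xs, ys):
    return np.column_stack([np.asarray(xs, float), np.asarray(ys, float)])


# ---------------------------------------------------------------------------
# nearest-neighbour distances
# ---------------------------------------------------------------------------

def test_nnd_collinear_example():
    pos = _cfg([0, 0, 0], [0, 40, 100])
    np.testing.assert_allclose(nearest_neighbor_distances(pos), [40, 40, 60])


def test_nnd_permutation_invariant(rng):
    pos = rng.uniform(-50, 50, (10, 2))
    perm = rng.permutation(10)
    a = nearest_neighbor_distances(pos)
    b = nearest_neighbor_distances(pos[perm])
    np.testing.assert_allclose(b, a[perm])


def test_nnd_requires_two_nuclei():
    with pytest.raises(ValueError):
        nearest_neighbor_distances(np.array([[0.0, 0.0]]))


def test_sparser_random_cells_have_larger_mean_nnd():
    """Ensemble mean NND decreases with the number of nuclei at fixed area."""
    g9 = CellGeometry(25, 250, 9)
    g15 = CellGeometry(25, 250, 15)
    base9 = random_nnd_baseline(g9, n_real=300, seed=5)
    base15 = random_nnd_baseline(g15, n_real=300, seed=5)
    assert base9.mean_nnd > base15.mean_nnd


def test_random_baseline_is_deterministic_and_tightens():
    geom = CellGeometry(25, 250, 9)
    a = random_nnd_baseline(geom, n_real=100, seed=3)
    b = random_nnd_baseline(geom, n_real=100, seed=3)
    np.testing.assert_array_equal(a.mean_counts, b.mean_counts)
    assert a.sd_nnd == b.sd_nnd
    # SEM of the mean curve shrinks with more realizations
    big = random_nnd_baseline(geom, n_real=1000, seed=3)
    assert big.sd_nnd / np.sqrt(big.n_realizations) < a.sd_nnd / np.sqrt(a.n_realizations)
    with pytest.raises(ValueError):
        random_nnd_baseline(CellGeometry(25, 250, 1), n_real=10)


# ---------------------------------------------------------------------------
# SF / DF classification
# ---------------------------------------------------------------------------

def test_central_file_is_sf():
    geom = CellGeometry(25, 250, 9)
    pos = _cfg(np.zeros(9), np.linspace(-200, 200, 9))
    assert classify_pattern(pos, geom).label == "SF"


def test_balanced_zigzag_is_df():
    geom = CellGeometry(40, 250, 14)
    xs = np.tile([-20.0, 20.0], 7)
    pos = _cfg(xs, np.linspace(-220, 220, 14))
    lab = classify_pattern(pos, geom)
    assert lab.label == "DF"
    assert len(lab.peak_bins) == 2


def test_scattered_pattern_is_neither():
    # 5 + 3 nuclei in two peak bins is 8/14 = 57% < 60%
    geom = CellGeometry(40, 250, 14)
    xs = np.concatenate([
        np.full(5, -20.0), np.full(3, 20.0),
        [-38, -10, -3, 3, 10, 38],
    ])
    pos = _cfg(xs, np.linspace(-220, 220, 14))
    assert classify_pattern(pos, geom).label == "neither"


def test_adjacent_peaks_do_not_make_a_double_file():
    geom = CellGeometry(40, 250, 10)
    # one broad file straddling two adjacent bins
    xs = np.tile([2.0, 9.0], 5)  # bins 3 and 4 (x/b = 0.05 and 0.225)
    pos = _cfg(xs, np.linspace(-200, 200, 10))
    assert classify_pattern(pos, geom).label != "DF"


def test_classification_invariances(rng):
    geom = CellGeometry(40, 250, 12)
    pos = _cfg(rng.uniform(-35, 35, 12), rng.uniform(-230, 230, 12))
    lab = classify_pattern(pos, geom).label
    # mirror in x
    assert classify_pattern(pos * [-1, 1], geom).label == lab
    # uniform rescaling of cell and positions
    geom2 = CellGeometry(80, 500, 12)
    assert classify_pattern(pos * 2.0, geom2).label == lab


# ---------------------------------------------------------------------------
# positional histograms and mean |x|
# ---------------------------------------------------------------------------

def test_single_central_nucleus_occupies_central_bins():
    geom = CellGeometry(40, 250, 1)
    hist = positional_histograms([(geom, np.array([[0.0, 0.0]]))], n_bins=9)
    assert hist.x_density[4] == 1.0
    assert hist.y_density[4] == 1.0


def test_histograms_reflection_invariant(rng):
    geom = CellGeometry(40, 250, 10)
    pos = _cfg(rng.uniform(-35, 35, 10), rng.uniform(-230, 230, 10))
    a = positional_histograms([(geom, pos)])
    b = positional_histograms([(geom, pos * [-1, 1])])
    np.testing.assert_allclose(b.x_density, a.x_density[::-1])
    np.testing.assert_allclose(b.y_density, a.y_density)


def test_mean_abs_x_on_ideal_files():
    geom = CellGeometry(40, 250, 8)
    sf = _cfg(np.zeros(8), np.linspace(-200, 200, 8))
    df = _cfg(np.tile([-15.0, 15.0], 4), np.linspace(-200, 200, 8))
    assert mean_abs_x(sf, geom) == 0.0
    assert mean_abs_x(df, geom) == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# zigzag correlations
# ---------------------------------------------------------------------------

def _integer_mass(res):
    on = res.counts[np.isclose(res.bin_centers % 1, 0)].sum()
    return on / max(res.counts.sum(), 1)


def _half_integer_mass(res):
    on = res.counts[np.isclose(res.bin_centers % 1, 0.5)].sum()
    return on / max(res.counts.sum(), 1)


def _df_cell(n_per_row, lam, x0, aligned):
    """Perfect double file: zigzag (aligned=False) or paired rows."""
    y_left = np.arange(n_per_row) * 2 * lam
    y_right = y_left.copy() if aligned else y_left + lam
    pos = np.concatenate([
        np.column_stack([np.full(n_per_row, -x0), y_left]),
        np.column_stack([np.full(n_per_row, x0), y_right]),
    ])
    pos[:, 1] -= pos[:, 1].mean()
    l = (pos[:, 1].max() + 3 * lam)
    geom = CellGeometry(2.5 * x0, max(l, 2.6 * x0), 2 * n_per_row)
    return geom, pos


def test_equispaced_single_file_autocorrelation_peaks_at_integers():
    lam = 40.0
    y = np.arange(12) * lam
    y -= y.mean()
    geom = CellGeometry(30, y.max() + 3 * lam, 12)
    pos = _cfg(np.zeros(12), y)
    corr = zigzag_correlations([(geom, pos)], labels=["SF"])
    res = corr["auto_SF"]
    assert not res.empty
    assert _integer_mass(res) == pytest.approx(1.0)


def test_perfect_zigzag_cross_correlation_peaks_at_integers():
    geom, pos = _df_cell(8, 20.0, 15.0, aligned=False)
    corr = zigzag_correlations([(geom, pos)], labels=["DF"])
    assert _integer_mass(corr["cross_DF"]) == pytest.approx(1.0)
    assert _integer_mass(corr["auto_DF_row"]) == pytest.approx(1.0)


def test_paired_rows_cross_correlation_peaks_at_half_integers():
    geom, pos = _df_cell(8, 20.0, 15.0, aligned=True)
    corr = zigzag_correlations([(geom, pos)], labels=["DF"])
    assert _half_integer_mass(corr["cross_DF"]) == pytest.approx(1.0)


def test_autocorrelation_histogram_is_symmetric():
    geom, pos = _df_cell(6, 25.0, 12.0, aligned=False)
    res = zigzag_correlations([(geom, pos)], labels=["DF"])["auto_DF_row"]
    np.testing.assert_array_equal(res.counts, res.counts[::-1])


def test_missing_pattern_kind_is_flagged_empty():
    geom, pos = _df_cell(6, 25.0, 12.0, aligned=False)
    corr = zigzag_correlations([(geom, pos)], labels=["DF"])
    assert corr["auto_SF"].empty
    assert not corr["cross_DF"].empty


def test_pole_trimming_drops_polar_nuclei():
    lam = 40.0
    y = np.arange(10) * lam
    y -= y.mean()
    geom = CellGeometry(30, 200.0, 10)  # 10% of height = 40 um
    pos = _cfg(np.zeros(10), np.clip(y, -195, 195))
    corr = zigzag_correlations([(geom, pos)], labels=["SF"], max_offset=12.0)
    # offsets beyond +-(kept range) cannot appear
    kept = np.abs(pos[:, 1]) <= 200 - 0.1 * 400
    assert corr["auto_SF"].counts.sum() == kept.sum() * (kept.sum() - 1)


# ---------------------------------------------------------------------------
# nuclear ellipses
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "major, minor, phi, expected",
    [
        (10.0, 5.0, np.pi / 2, 2.0),   # elongated along the cell axis
        (10.0, 5.0, 0.0, 0.5),         # across the cell axis: reciprocal
        (6.0, 6.0, 1.0, 1.0),          # circle at any angle
        (10.0, 5.0, np.pi / 2 - np.pi / 4, 2.0),  # boundary of the branch
    ],
)
def test_oriented_aspect_ratio_branches(major, minor, phi, expected):
    e = NuclearEllipse((0.0, 0.0), major, minor, phi)
    assert aspect_ratio_from_ellipse(e) == pytest.approx(expected)


def test_ellipse_validation():
    with pytest.raises(ValueError):
        NuclearEllipse((0, 0), 5.0, 10.0, 0.0)  # major < minor
    with pytest.raises(ValueError):
        NuclearEllipse((0, 0), 10.0, 5.0, 4.0)  # angle out of [0, pi)
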