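"""Composite scoring, geometric-interval classification and structure tests."""

import numpy as np
import pytest
from shapely.geometry import box

from epirisk.fishnet import make_fishnet
from epirisk.overlay import (
    RiskMap,
    classify,
    composite_score,
    geometric_interval_breaks,
    spatial_structure,
    validate_sites,
)
from epirisk.weighting import WeightVector


def _wv(*weights):
    w = np.array(weights, float)
    return WeightVector(weights=w, entropies=1.0 - w)


class TestCompositeScore:
    def test_bounds_and_linearity(self):
        w = _wv(0.2, 0.3, 0.5)
        ones = composite_score(np.ones((4, 3)), w)
        zeros = composite_score(np.zeros((4, 3)), w)
        assert ones == pytest.approx([1.0] * 4)
        assert zeros == pytest.approx([0.0] * 4)
        onehot = np.eye(3)
        assert composite_score(onehot, w) == pytest.approx(w.weights)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            composite_score(np.ones((4, 3)), _wv(0.5, 0.5))

    def test_monotone_in_each_indicator(self):
        rng = np.random.default_rng(0)
        x = rng.random((10, 3))
        w = _wv(0.2, 0.3, 0.5)
        base = composite_score(x, w)
        for j in range(3):
            bumped = x.copy()
            bumped[:, j] = np.minimum(1.0, bumped[:, j] + 0.1)
            assert np.all(composite_score(bumped, w) >= base - 1e-12)


class TestGeometricIntervalBreaks:
    def test_forced_ratio_closed_form(self):
        v = np.linspace(0, 15, 100)
        breaks = geometric_interval_breaks(v, k=4, g=2.0)
        assert breaks == pytest.approx([1.0, 3.0, 7.0, 15.0])

    def test_uniform_values_select_equal_intervals(self):
        v = np.linspace(0, 1, 500)
        breaks = geometric_interval_breaks(v, k=5)
        widths = np.diff(np.concatenate([[0.0], breaks]))
        assert widths == pytest.approx([0.2] * 5, rel=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_right_skew_selects_growing_widths(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.lognormal(0.0, 1.0, size=2000)
        breaks = geometric_interval_breaks(v, k=5)
        widths = np.diff(np.concatenate([[v.min()], breaks]))
        g_hat = widths[1] / widths[0]
        assert g_hat > 1.0

    def test_too_few_distinct_values_falls_back_to_quantiles(self):
        with pytest.warns(UserWarning, match="quantile"):
            breaks = geometric_interval_breaks(np.array([1.0, 1.0, 2.0, 2.0]), k=5)
        assert len(breaks) == 5


class TestClassify:
    def test_extremes_and_tie_rule(self):
        breaks = np.array([1.0, 3.0, 7.0, 15.0])
        v = np.array([0.0, 15.0, 3.0, 2.9, 1.0])
        cls = classify(v, breaks)
        assert cls[0] == 4  # minimum -> lowest-risk class (k = 4 here)
        assert cls[1] == 1  # maximum -> class 1
        assert cls[2] == 2  # exactly on a break -> riskier side
        assert cls[3] == 3
        assert cls[4] == 3

    def test_affine_invariance_with_breaks(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(0, 0.8, size=300)
        c1 = classify(v, geometric_interval_breaks(v, k=5))
        v2 = 4.0 * v + 11.0
        c2 = classify(v2, geometric_interval_breaks(v2, k=5))
        assert np.array_equal(c1, c2)


def _riskmap_from_class1(cells, shape=(12, 14)):
    """RiskMap fixture with the given (row, col) cells as class 1."""
    fn = make_fishnet(box(0, 0, shape[1] * 1000, shape[0] * 1000), 1000)
    classes = np.full(len(fn), 5)
    lut = {(r, c): i for i, (r, c) in enumerate(zip(fn.rows, fn.cols))}
    for rc in cells:
        classes[lut[rc]] = 1
    scores = 1.0 - (classes - 1) / 4.0
    return RiskMap(
        fishnet=fn, scores=scores, classes=classes, breaks=np.linspace(0.2, 1.0, 5)
    )


class TestSpatialStructure:
    def test_single_blob_is_main(self):
        cells = [(r, c) for r in range(2, 5) for c in range(2, 5)] + [(5, 2)]
        st = spatial_structure(_riskmap_from_class1(cells))
        assert st.counts == {"main": 1, "secondary": 0, "belt": 0, "point": 0}

    def test_main_secondary_point(self):
        blob10 = [(r, c) for r in range(0, 2) for c in range(0, 5)]
        blob6 = [(r, c) for r in range(6, 8) for c in range(0, 3)]
        lone = [(10, 12)]
        st = spatial_structure(_riskmap_from_class1(blob10 + blob6 + lone))
        assert st.counts == {"main": 1, "secondary": 1, "belt": 0, "point": 1}

    def test_chain_labeled_belt(self):
        blob = [(r, c) for r in range(0, 4) for c in range(0, 4)]  # 16 cells: main
        chain = [(10, c) for c in range(0, 12)]  # 1 x 12 chain
        st = spatial_structure(_riskmap_from_class1(blob + chain))
        assert st.counts["main"] == 1
        assert st.counts["belt"] == 1
        comp = st.components
        belt = comp[comp["kind"] == "belt"].iloc[0]
        assert belt["elongation"] >= 4.0
        assert belt["n_cells"] == 12

    def test_no_class1_cells_empty_structure(self):
        st = spatial_structure(_riskmap_from_class1([]))
        assert len(st.components) == 0
        assert st.counts == {"main": 0, "secondary": 0, "belt": 0, "point": 0}

    def test_eight_vs_four_connectivity(self):
        diag = [(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5)]
        st8 = spatial_structure(_riskmap_from_class1(diag), connectivity=8)
        st4 = spatial_structure(_riskmap_from_class1(diag), connectivity=4)
        assert len(st8.components) == 1
        assert len(st4.components) == 6


class TestValidateSites:
    def test_no_sites(self):
        rm = _riskmap_from_class1([(0, 0)])
        v = validate_sites(np.empty((0, 2)), rm)
        assert v.n_in_grid == 0
        assert v.coverage_top2 == 0.0

    def test_all_sites_in_class1_cells(self):
        rm = _riskmap_from_class1([(2, 3), (5, 6)])
        sites = np.array([[3500.0, 2500.0], [6500.0, 5500.0]])
        v = validate_sites(sites, rm)
        assert v.class_counts[1] == 2
        assert v.coverage_top2 == 1.0

    def test_outside_sites_counted_separately(self):
        rm = _riskmap_from_class1([(0, 0)])
        v = validate_sites(np.array([[-10.0, -10.0], [500.0, 500.0]]), rm)
        assert v.n_outside == 1
        assert v.n_in_grid == 1
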