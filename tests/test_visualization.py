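import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciber.estimation import AssociationEstimate, EstimateWithCI, estimate_all
from ciber.synthetic import case_study_config, generate_likert_dataset
from ciber.visualization import (
    BLUE,
    GRAY,
    GREEN,
    RED,
    PlotError,
    PlotOptions,
    RelevanceThresholds,
    assoc_color,
    build_ciber_plot,
    classify_relevance,
    estimate_count,
    jitter_points,
    mean_color,
    order_items,
    render,
)


class TestColorMaps:
    @pytest.mark.parametrize(
        "mean,expected", [(1, RED), (4, BLUE), (7, GREEN)],
        ids=["low-end-red", "midpoint-blue", "high-end-green"],
    )
    def test_mean_color_endpoints_exact_on_7_point_scale(self, mean, expected):
        assert mean_color(mean, 1, 7) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "r,expected", [(-1, RED), (0, GRAY), (1, GREEN)],
        ids=["negative-red", "zero-gray", "positive-green"],
    )
    def test_assoc_color_endpoints_exact(self, r, expected):
        assert assoc_color(r) == pytest.approx(expected)

    @pytest.mark.parametrize("cmap,domain", [
        (lambda v: mean_color(v, 1, 7), np.linspace(1, 7, 201)),
        (assoc_color, np.linspace(-1, 1, 201)),
    ], ids=["mean-map", "assoc-map"])
    def test_channel_monotonicity_and_continuity(self, cmap, domain):
        colors = np.array([cmap(v) for v in domain])
        red, green = colors[:, 0], colors[:, 1]
        assert np.all(np.diff(red) <= 1e-12)  # red never increases
        assert np.all(np.diff(green) >= -1e-12)  # green never decreases
        assert np.max(np.abs(np.diff(colors, axis=0))) < 0.02  # no jumps

    def test_out_of_domain_rejected(self):
        with pytest.raises(PlotError):
            mean_color(0.5, 1, 7)
        with pytest.raises(PlotError):
            assoc_color(1.5)


class TestJitter:
    def test_zero_spread_points_exactly_at_scores(self):
        pts = jitter_points([2, 5, 7], seed=1, h_spread=0, v_spread=0)
        np.testing.assert_array_equal(pts, [[2, 0], [5, 0], [7, 0]])

    def test_same_seed_identical_offsets(self):
        a = jitter_points(np.arange(50.0), seed=9)
        b = jitter_points(np.arange(50.0), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_one_point_per_nonmissing_score(self, rng):
        scores = rng.integers(1, 8, 227).astype(float)
        scores[:10] = np.nan
        assert jitter_points(scores).shape == (217, 2)

    def test_offsets_bounded_by_spreads(self, rng):
        scores = np.full(1000, 4.0)
        pts = jitter_points(scores, seed=3, h_spread=0.45, v_spread=0.2)
        assert np.all(np.abs(pts[:, 0] - 4.0) <= 0.45)
        assert np.all(np.abs(pts[:, 1]) <= 0.2)


def _results_with(means: dict[str, float], assoc: dict[str, dict[str, float]] | None = None):
    """Hand-built EstimationResults for ordering tests."""
    from ciber.estimation import EstimationResults

    assoc = assoc or {}
    targets = sorted({t for m in assoc.values() for t in m})
    res = EstimationResults(list(means), targets)
    for item, m in means.items():
        res.means[item] = EstimateWithCI(m, m - 0.5, m + 0.5, 0.95, 50)
    for item, per_target in assoc.items():
        for t, r in per_target.items():
            res.associations.append(
                AssociationEstimate(item, t, EstimateWithCI(r, r - 0.1, r + 0.1, 0.95, 50))
            )
    return res


class TestOrderItems:
    def test_by_association_descending(self):
        res = _results_with(
            {"a": 3, "b": 3, "c": 3},
            {"a": {"t": 0.5}, "b": {"t": -0.2}, "c": {"t": 0.8}},
        )
        assert order_items(res, "by-association", "t") == ["c", "a", "b"]

    def test_mean_ties_keep_input_order(self):
        res = _results_with({"a": 3, "b": 3})
        assert order_items(res, "by-mean-descending") == ["a", "b"]
        assert order_items(res, "by-mean-ascending") == ["a", "b"]

    def test_mean_ordering_directions(self):
        res = _results_with({"a": 2, "b": 5, "c": 4})
        assert order_items(res, "by-mean-descending") == ["b", "c", "a"]
        assert order_items(res, "by-mean-ascending") == ["a", "c", "b"]

    def test_unknown_target_rejected(self):
        res = _results_with({"a": 1})
        with pytest.raises(PlotError):
            order_items(res, "by-association", "nope")

    @given(st.lists(st.floats(1, 7), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_always_a_permutation(self, means):
        res = _results_with({f"i{k}": m for k, m in enumerate(means)})
        out = order_items(res, "by-mean-descending")
        assert sorted(out) == sorted(res.determinant_ids)


def _assoc(item, target, r):
    return AssociationEstimate(item, target, EstimateWithCI(r, r - 0.08, r + 0.08, 0.95, 227))


def _mean(m):
    return EstimateWithCI(m, m - 0.2, m + 0.2, 0.9999, 227)


class TestClassifyRelevance:
    """The four canonical univariate/bivariate relevance patterns."""

    def test_strong_positive_association_mid_scale_mean_is_negate(self):
        cls = classify_relevance(_mean(4.0), 1, 7, [_assoc("i", "attitude", 0.45)])
        assert (cls.label, cls.action) == ("relevant-negate", "negate")
        assert not cls.low_confidence

    def test_strong_negative_association_mid_scale_mean_is_reinforce(self):
        cls = classify_relevance(_mean(3.9), 1, 7, [_assoc("i", "attitude", -0.45)])
        assert (cls.label, cls.action) == ("relevant-reinforce", "reinforce")

    def test_strong_association_mean_at_safe_extreme_is_confirm(self):
        cls = classify_relevance(_mean(1.6), 1, 7, [_assoc("i", "attitude", 0.45)])
        assert (cls.label, cls.action) == ("already-favorable", "confirm")

    def test_weak_association_any_mean_is_deprioritized(self):
        for m in (1.5, 4.0, 6.5):
            cls = classify_relevance(
                _mean(m), 1, 7,
                [_assoc("i", "attitude", 0.02), _assoc("i", "intention", 0.06)],
            )
            assert (cls.label, cls.action) == ("unassociated", "deprioritize")

    def test_ambiguous_band_flagged_low_confidence(self):
        cls = classify_relevance(_mean(4.0), 1, 7, [_assoc("i", "attitude", 0.2)])
        assert cls.label == "relevant-negate"
        assert cls.low_confidence

    def test_driving_target_is_strongest_association(self):
        cls = classify_relevance(
            _mean(4.0), 1, 7,
            [_assoc("i", "attitude", 0.1), _assoc("i", "intention", -0.5)],
        )
        assert cls.driving_target == "intention"
        assert cls.label == "relevant-reinforce"

    def test_reversed_target_coding_flips_orientation(self):
        thr = RelevanceThresholds(target_high_undesirable=False)
        cls = classify_relevance(_mean(4.0), 1, 7, [_assoc("i", "t", 0.45)], thr)
        assert cls.label == "relevant-reinforce"

    def test_patterns_reproduced_on_generated_study(self):
        # At n=2000 sampling noise cannot blur the four built-in exemplars.
        cfg = case_study_config(seed=11, n_respondents=2000)
        ds, _, _ = generate_likert_dataset(cfg)
        res = estimate_all(ds, cfg.item_names, cfg.target_names)
        expected = {
            "belief_01": "relevant-negate",
            "belief_02": "already-favorable",
            "belief_15": "unassociated",
            "belief_21": "relevant-reinforce",
        }
        for item, label in expected.items():
            cls = classify_relevance(
                res.means[item], 1, 7, res.associations_for_item(item)
            )
            assert cls.label == label, item


class TestEstimateCount:
    @pytest.mark.parametrize("items,targets,expected", [(10, 1, 60), (0, 5, 0), (21, 2, 189)])
    def test_counting_formula(self, items, targets, expected):
        assert estimate_count(items, targets) == expected


@pytest.fixture(scope="module")
def study():
    cfg = case_study_config(seed=7)
    ds, meta, _ = generate_likert_dataset(cfg)
    return cfg, ds, meta


@pytest.fixture(scope="module")
def study_spec(study):
    cfg, ds, meta = study
    return build_ciber_plot(
        ds, cfg.item_names, cfg.target_names, metadata=meta,
        options=PlotOptions(order_mode="by-association", order_target="attitude"),
    )


class TestBuildPlot:
    def test_case_study_layout(self, study_spec):
        assert len(study_spec.rows) == 21
        assert sum(len(g) for g in study_spec.right_diamonds) == 42
        assert len(study_spec.banner) == 2
        assert study_spec.displayed_estimate_count() == 21 * 3 * (1 + 2)

    def test_rows_ordered_by_attitude_association(self, study, study_spec):
        cfg, ds, _ = study
        res = estimate_all(ds, cfg.item_names, cfg.target_names)
        points = [
            res.association(r.item_id, "attitude").estimate.point for r in study_spec.rows
        ]
        assert points == sorted(points, reverse=True)

    def test_no_targets_left_panel_only(self, study):
        cfg, ds, meta = study
        spec = build_ciber_plot(ds, cfg.item_names, [], metadata=meta)
        assert spec.right_diamonds == [[] for _ in range(21)]
        assert spec.banner == []
        assert len(spec.left_diamonds) == 21

    def test_diamonds_respect_interval_geometry(self, study_spec):
        for d in study_spec.left_diamonds + [g for row in study_spec.right_diamonds for g in row]:
            assert d.left_x <= d.center_x <= d.right_x

    def test_unavailable_item_kept_as_labeled_row(self, study):
        cfg, ds, _ = study
        frame = ds.data.copy()
        frame["dead"] = np.nan
        from ciber.data_io import QuestionnaireDataset

        spec = build_ciber_plot(
            QuestionnaireDataset(frame), cfg.item_names + ["dead"], cfg.target_names
        )
        dead_rows = [r for r in spec.rows if r.item_id == "dead"]
        assert len(dead_rows) == 1 and not dead_rows[0].available
        assert len(spec.left_diamonds) == 21

    def test_spec_serializes_to_json(self, study_spec):
        import json

        blob = json.loads(study_spec.to_json())
        assert len(blob["rows"]) == 21
        assert blob["scale_min"] == 1 and blob["scale_max"] == 7


class TestRender:
    def test_minimal_spec_written_as_svg(self, tmp_path, small_dataset):
        spec = build_ciber_plot(small_dataset, ["item_a"], [])
        out = render(spec, tmp_path / "one.svg")
        text = out.read_text()
        assert text.startswith("<?xml")
        assert "<svg" in text

    def test_identical_spec_renders_byte_identical_svg(self, tmp_path, study_spec):
        a = render(study_spec, tmp_path / "a.svg")
        b = render(study_spec, tmp_path / "b.svg")
        assert a.read_bytes() == b.read_bytes()

    def test_unsupported_format_rejected(self, tmp_path, study_spec):
        with pytest.raises(PlotError, match="unsupported format"):
            render(study_spec, tmp_path / "x.bmp", fmt="bmp")

    @pytest.mark.parametrize("fmt", ["png", "pdf"])
    def test_raster_and_pdf_outputs_written(self, tmp_path, small_dataset, fmt):
        spec = build_ciber_plot(small_dataset, ["item_a", "item_b"], ["outcome"])
        out = render(spec, tmp_path / f"fig.{fmt}")
        assert out.stat().st_size > 0
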