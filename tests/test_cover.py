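"""Cover tables, resampling medians, aggregation and the area-bias check."""

import numpy as np
import pandas as pd
import pytest

import reefquad as rq
from reefquad.annotate import PointAnnotation
from reefquad.cover import CoverUndefinedError, cover_table, image_cover


def _pt(label, row=0, col=0):
    return PointAnnotation("img", row, col, final_label=label, status="manual",
                           manual_label=label)


def test_all_coral_image():
    tab = image_cover([_pt("SC", 0, i) for i in range(25)])
    assert tab.loc[0, "label"] == "SC"
    assert tab.loc[0, "cover"] == 1.0
    assert tab.loc[0, "n_points_included"] == 25


def test_quality_labels_excluded_and_renormalized():
    pts = (
        [_pt("TAPE", 0, i) for i in range(2)]
        + [_pt("SC", 1, i) for i in range(4)]
        + [_pt("SAND", 2, i) for i in range(4)]
    )
    tab = image_cover(pts).set_index("label")
    assert tab.loc["SC", "cover"] == 0.5
    assert tab.loc["SAND", "cover"] == 0.5
    assert (tab["n_points_included"] == 8).all()


def test_cover_sums_to_one_after_exclusion(coral_sand_scene, finalize):
    img, truth = coral_sand_scene
    pts = rq.generate_points(img, 100, seed=0)
    tab = image_cover(finalize(pts, truth))
    assert tab["cover"].sum() == pytest.approx(1.0, abs=1e-9)


def test_zero_benthic_points_flagged_not_dropped():
    with pytest.raises(CoverUndefinedError):
        image_cover([_pt("TAPE"), _pt("SHAD")])
    tabs = cover_table({"good": [_pt("SC")], "bad": [_pt("TAPE")]})
    assert tabs.attrs["undefined_images"] == ["bad"]
    assert set(tabs["image_id"]) == {"good"}


def test_point_count_cover_unbiased(coral_sand_30_70, finalize):
    """Perfect annotation of 1e4 points estimates the 30% coral fraction
    within 3 binomial SE of the ground-truth fraction."""
    img, truth = coral_sand_30_70
    pts = rq.generate_points(img, 10_000, seed=1)
    tab = image_cover(finalize(pts, truth, accuracy=1.0)).set_index("label")
    want = truth.class_fractions_interior["SC"]
    sigma = np.sqrt(want * (1 - want) / 10_000)
    assert abs(tab.loc["SC", "cover"] - want) <= 3 * sigma


def _cover_frame(values_by_image):
    rows = []
    for image_id, labels in values_by_image.items():
        for label, cov in labels.items():
            rows.append({"image_id": image_id, "label": label, "cover": cov})
    return pd.DataFrame(rows)


def test_resample_median_constant_data_exact():
    cov = _cover_frame({f"im{i}": {"SC": 0.2, "SAND": 0.8} for i in range(80)})
    med = rq.resample_median_cover(cov, n_sub=20, n_iter=50, seed=0)
    assert med["SC"] == pytest.approx(0.2, abs=1e-12)
    assert med["SAND"] == pytest.approx(0.8, abs=1e-12)


def test_resample_with_all_images_equals_plain_mean():
    rng = np.random.default_rng(0)
    cov = _cover_frame({f"im{i}": {"SC": rng.uniform(0, 0.4)} for i in range(30)})
    med = rq.resample_median_cover(cov, n_sub=30, n_iter=10, seed=0)
    grand = cov["cover"].mean()
    assert med["SC"] == pytest.approx(grand, abs=1e-12)


def test_resample_concentrates_on_grand_mean():
    rng = np.random.default_rng(1)
    cov = _cover_frame({f"im{i:02d}": {"SC": rng.uniform(0, 0.4)} for i in range(80)})
    med = rq.resample_median_cover(cov, n_sub=20, n_iter=1000, seed=2)
    assert abs(med["SC"] - cov["cover"].mean()) <= 0.01


def test_resample_invariant_to_image_order():
    rng = np.random.default_rng(3)
    cov = _cover_frame({f"im{i:02d}": {"SC": rng.uniform(0, 0.4)} for i in range(40)})
    shuffled = cov.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = rq.resample_median_cover(cov, n_sub=20, n_iter=100, seed=5)
    b = rq.resample_median_cover(shuffled, n_sub=20, n_iter=100, seed=5)
    pd.testing.assert_series_equal(a, b)


def test_resample_too_few_images_instructs_plain_mean():
    cov = _cover_frame({f"im{i}": {"SC": 0.1} for i in range(5)})
    with pytest.raises(ValueError, match="plain mean"):
        rq.resample_median_cover(cov, n_sub=20)


def _manifest(images, site="CBC Lagoon Reef", year=2014):
    return [rq.QuadratRecord(image_id=i, site=site, year=year) for i in images]


def test_site_year_single_image_has_no_se():
    cov = _cover_frame({"a": {"SC": 0.2}})
    agg = rq.site_year_cover(cov, _manifest(["a"]))
    assert np.isnan(agg["se"]).all()


def test_site_year_mean_and_se_hand_arithmetic():
    cov = _cover_frame({"a": {"SC": 0.1}, "b": {"SC": 0.3}})
    agg = rq.site_year_cover(cov, _manifest(["a", "b"])).set_index("label")
    assert agg.loc["SC", "cover"] == pytest.approx(0.2)
    assert agg.loc["SC", "se"] == pytest.approx(0.1)
    assert agg.loc["SC", "reef_type"] == "patch"


def test_aggregation_recovers_generator_means():
    """Site-year means of simulated per-image cover bracket the
    generator's true inverse-logit mean within 3 SE in >= 95% of cases."""
    hits = total = 0
    for rep in range(60):
        df = rq.simulate_cover_series(
            4, trend={"SC": 0.0}, seed=3000 + rep, n_images=20, site_sd=0.0
        )
        agg = df.groupby(["site", "year"])["cover"].agg(["mean", "std", "count"])
        se = agg["std"] / np.sqrt(agg["count"])
        inside = (agg["mean"] - 0.10).abs() <= 3 * se
        hits += inside.sum()
        total += len(agg)
    assert hits / total >= 0.95


def test_area_bias_detects_real_dependence():
    """Cover built as 0.1*log10(area) + noise yields a significant
    positive slope at the survey's n=42 images."""
    rng = np.random.default_rng(4)
    areas = {f"im{i:02d}": a for i, a in enumerate(rng.uniform(0.3, 1.5, 42))}
    rows = {
        i: {"SC": float(np.clip(0.3 + 0.1 * np.log10(a) + rng.normal(0, 0.03), 0, 1))}
        for i, a in areas.items()
    }
    res = rq.area_bias_check(_cover_frame(rows), areas).set_index("label")
    assert res.loc["SC", "slope"] > 0
    assert res.loc["SC", "p_value"] < 0.05


def test_area_bias_excludes_rare_labels():
    rng = np.random.default_rng(5)
    areas = {f"im{i}": a for i, a in enumerate(rng.uniform(0.3, 1.5, 20))}
    rows = {
        i: {"SC": rng.uniform(0.2, 0.4), "SP": 0.005} for i in areas
    }
    res = rq.area_bias_check(_cover_frame(rows), areas)
    assert set(res["label"]) == {"SC"}


def test_area_bias_identical_areas_error():
    cov = _cover_frame({f"im{i}": {"SC": 0.2} for i in range(5)})
    with pytest.raises(ValueError, match="identical"):
        rq.area_bias_check(cov, {f"im{i}": 0.74 for i in range(5)})


def test_quadrat_record_defaults_and_validation():
    rec = rq.QuadratRecord("x", "South Reef Central", 2016)
    assert rec.reef_type == "forereef"
    assert rec.transect_type == "fixed"
    with pytest.raises(ValueError):
        rq.QuadratRecord("x", "Nowhere Reef", 2016)
    with pytest.raises(ValueError):
        rq.QuadratRecord("x", "Tobacco Reef", 2016, area_m2=-1.0)
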