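"""Community matrix, NMDS and the native RDA permutation ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

import reefquad as rq


def _sim_cover(seed=0, trend=None, site_sd=0.5):
    trend = trend or {"SC": 0.0, "MA": 0.0, "CS": 0.0, "OCT": 0.0, "SP": 0.0, "LTA": 0.0}
    base = {"SC": 0.08, "MA": 0.1, "CS": 0.5, "OCT": 0.12, "SP": 0.03, "LTA": 0.05}
    df = rq.simulate_cover_series(6, trend=trend, baseline=base, seed=seed,
                                  site_sd=site_sd)
    return df[["site", "year", "reef_type", "label", "cover"]]


def test_build_matrix_sqrt_and_shape():
    cov = _sim_cover()
    m = rq.build_matrix(cov)
    assert m.shape == (30, 6)
    one = cov.iloc[0]
    row = m.meta.index[(m.meta["site"] == one["site"]) & (m.meta["year"] == one["year"])][0]
    assert m.values.iloc[row][one["label"]] == pytest.approx(np.sqrt(one["cover"]))


def test_build_matrix_literal_entries():
    cov = pd.DataFrame(
        {"site": ["a", "a", "b", "b"], "year": [1, 1, 1, 1],
         "label": ["SC", "MA", "SC", "MA"], "cover": [0.25, 0.0, 0.04, 0.81]}
    )
    m = rq.build_matrix(cov)
    got = m.values.to_numpy()
    assert got[0].tolist() == pytest.approx([0.0, 0.5])  # columns sorted: MA, SC
    assert got[1].tolist() == pytest.approx([0.9, 0.2])


def test_build_matrix_rejects_duplicates():
    cov = pd.DataFrame(
        {"site": ["a", "a"], "year": [1, 1], "label": ["SC", "SC"], "cover": [0.1, 0.2]}
    )
    with pytest.raises(ValueError, match="duplicate"):
        rq.build_matrix(cov)


def _toy_matrix(rows, labels=("SC", "MA", "CS")):
    recs = []
    for i, vals in enumerate(rows):
        for lab, v in zip(labels, vals):
            recs.append({"site": f"s{i}", "year": 1, "label": lab, "cover": v})
    return rq.build_matrix(pd.DataFrame(recs))


def test_nmds_preserves_pair_structure():
    """Two tight pairs far apart in group space stay paired in the
    ordination: within-pair distances below between-pair distances."""
    m = _toy_matrix(
        [(0.8, 0.05, 0.05), (0.78, 0.06, 0.05), (0.05, 0.8, 0.05), (0.06, 0.79, 0.05)]
    )
    coords = rq.NMDSOrdination(seed=0).fit_transform(m)
    d = pdist(coords)  # order: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
    within = [d[0], d[5]]
    between = [d[1], d[2], d[3], d[4]]
    assert max(within) < min(between)


def test_nmds_duplicate_rows_coincide():
    m = _toy_matrix(
        [(0.8, 0.1, 0.1), (0.8, 0.1, 0.1), (0.1, 0.8, 0.1), (0.2, 0.2, 0.6),
         (0.5, 0.3, 0.2)]
    )
    # zero-dissimilarity pairs coincide in the limit; run to convergence
    coords = rq.NMDSOrdination(seed=1, eps=1e-12, max_iter=10_000).fit_transform(m)
    span = np.ptp(coords)
    assert np.linalg.norm(coords[0] - coords[1]) < 1e-6 * span + 1e-9


def test_nmds_stress_decreases_with_dimension():
    cov = _sim_cover(seed=3)
    m = rq.build_matrix(cov)
    s1 = rq.run_nmds(m, k=1, seed=0).stress
    s2 = rq.run_nmds(m, k=2, seed=0).stress
    assert s2 <= s1 + 1e-9


def test_nmds_deterministic_under_seed():
    m = rq.build_matrix(_sim_cover(seed=4))
    a = rq.run_nmds(m, seed=5)
    b = rq.run_nmds(m, seed=5)
    assert np.allclose(a.coords.filter(like="nmds"), b.coords.filter(like="nmds"))
    assert a.stress == b.stress


def test_nmds_degenerate_input_rejected():
    m = _toy_matrix([(0.3, 0.3, 0.4)] * 5)
    with pytest.raises(ValueError, match="identical"):
        rq.NMDSOrdination(seed=0).fit_transform(m)


def test_stress_interpretation_bands():
    assert "excellent" in rq.interpret_stress(0.05)
    assert rq.interpret_stress(0.15) == "good to excellent (0.1-0.2)"
    assert "poor" in rq.interpret_stress(0.3)


def test_rda_variance_decomposition_identity():
    m = rq.build_matrix(_sim_cover(seed=5))
    res = rq.rda_perm_anova(m, n_perm=49, seed=0)
    total = res.anova["variance"].sum() + res.residual_variance
    assert total == pytest.approx(res.total_variance, abs=1e-8)
    assert res.anova["variance_fraction"].sum() <= 1 + 1e-12


def test_rda_detects_injected_year_effect():
    trend = {lab: 0.35 for lab in ("SC", "MA", "CS", "OCT", "SP", "LTA")}
    m = rq.build_matrix(_sim_cover(seed=6, trend=trend))
    res = rq.rda_perm_anova(m, n_perm=999, seed=1)
    assert res.p_value("year") == 1.0 / 1000  # minimum attainable p
    assert (res.anova["p_value"] >= 1.0 / 1000).all()


def test_rda_p_invariant_to_row_order():
    cov = _sim_cover(seed=7)
    shuffled = cov.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = rq.rda_perm_anova(rq.build_matrix(cov), n_perm=99, seed=2)
    b = rq.rda_perm_anova(rq.build_matrix(shuffled), n_perm=99, seed=2)
    pd.testing.assert_frame_equal(a.anova, b.anova)


def test_rda_aliased_term_named():
    m = rq.build_matrix(_sim_cover(seed=8))
    with pytest.raises(ValueError, match="aliased"):
        rq.rda_perm_anova(m, terms=("locality", "reef_type", "year"), n_perm=9)


def test_rda_unknown_term_rejected():
    m = rq.build_matrix(_sim_cover(seed=9))
    with pytest.raises(ValueError, match="no column"):
        rq.rda_perm_anova(m, terms=("depth",), n_perm=9)
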