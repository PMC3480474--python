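import numpy as np
import pytest
from scipy import stats

from stpscan import (
    ArtificialCluster,
    RegionConfig,
    assemble_dataset,
    compute_C,
    compute_p,
    draw_cluster_geometry,
    draw_counts,
    inject_dataset,
    sample_controls,
    sample_treatments,
)
from stpscan.population import PopulationFrame


def toy_pool(points, width=12.0, height=12.0, months=4):
    cfg = RegionConfig(
        width_km=width, height_km=height, n_pool=len(points), n_blobs=0,
        blob_weight=0.0, months=months, seasonal_amplitude=0.0,
        n_zip_units=2, n_county_units=1, seed=0,
    )
    pts = np.asarray(points, float)
    return PopulationFrame(
        x=pts[:, 0], y=pts[:, 1],
        month=np.zeros(len(pts), np.int16),
        month_marginal=np.full(months, 1.0 / months),
        config=cfg,
    )


class TestGeometryDraws:
    def test_radius_support_and_uniformity(self, small_study):
        pop, _, _ = small_study
        rs = np.array(
            [draw_cluster_geometry(pop, seed)[1] for seed in range(10_000)]
        )
        assert rs.min() >= 1.6 and rs.max() <= 48.0
        frac_small = (rs <= 16.0).mean()
        expected = (16.0 - 1.6) / 46.4  # ~0.310
        se = np.sqrt(expected * (1 - expected) / len(rs))
        assert abs(frac_small - expected) < 4 * se

    def test_all_rr_values_occur_and_squares_fit(self, small_study):
        pop, _, _ = small_study
        cfg = pop.config
        seen = set()
        for seed in range(2_000):
            (cx, cy), r, rr, onset = draw_cluster_geometry(pop, seed)
            seen.add(rr)
            assert r <= cx <= cfg.width_km - r
            assert r <= cy <= cfg.height_km - r
            assert 0 <= onset <= cfg.months - 3
        assert seen == set(range(1, 11))

    def test_region_too_small_rejected(self):
        pool = toy_pool([(1.0, 1.0)])
        with pytest.raises(ValueError):
            draw_cluster_geometry(pool, 0)


class TestInsideProportion:
    def test_hand_counted_toy(self):
        pool = toy_pool([(1, 1), (3, 3), (9, 9), (9, 1)])
        assert compute_C(pool, (2.0, 2.0), 1.5) == pytest.approx(0.5)

    def test_full_and_empty_squares(self):
        pool = toy_pool([(2, 2), (5, 5), (8, 8)])
        assert compute_C(pool, (6.0, 6.0), 6.0) == 1.0
        with pytest.warns(UserWarning):
            assert compute_C(pool, (11.5, 11.5), 0.4) == 0.0


class TestExcessProbability:
    def test_null_rr_gives_zero(self):
        for C in (0.0, 0.05, 0.7, 1.0):
            assert compute_p(C, 1) == (0.0, 1.0)

    def test_formula_value(self):
        p, q = compute_p(0.05, 3)
        assert p == pytest.approx(0.05 * 2 / 0.95)  # ~0.10526
        assert q == pytest.approx(1 - p)

    def test_clamps_at_one(self):
        p, _ = compute_p(0.5, 10)  # raw 4.5
        assert p == 1.0
        assert compute_p(1.0, 5) == (1.0, 0.0)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            compute_p(-0.1, 2)
        with pytest.raises(ValueError):
            compute_p(0.5, 0)


class TestCounts:
    def test_degenerate_probabilities(self):
        assert draw_counts(0.0, 1) == (0, 1000)
        assert draw_counts(1.0, 1) == (1000, 0)

    def test_binomial_mean(self):
        draws = np.array([draw_counts(0.1, s)[0] for s in range(10_000)])
        se = np.sqrt(1000 * 0.1 * 0.9 / len(draws))
        assert abs(draws.mean() - 100.0) < 3 * se


class TestControlsAndTreatments:
    def test_controls_keep_coordinates_and_randomize_months(self, small_study):
        pop, _, _ = small_study
        ctrl = sample_controls(pop, 10_000, seed=3)
        pool_xy = set(zip(pop.x.tolist(), pop.y.tolist()))
        assert set(zip(ctrl["x"].tolist(), ctrl["y"].tolist())) <= pool_xy
        # months redrawn from the seasonal marginal, not the point's own
        obs = np.bincount(ctrl["month"], minlength=pop.config.months)
        chi = stats.chisquare(obs, pop.month_marginal * len(ctrl))
        assert chi.pvalue > 0.001

    def test_controls_empty_and_oversized(self, small_study):
        pop, _, _ = small_study
        assert len(sample_controls(pop, 0, seed=1)) == 0
        with pytest.raises(ValueError):
            sample_controls(pop, pop.n + 1, seed=1)

    def test_treatments_inside_square_and_window(self, small_study):
        _, zips, counties = small_study
        truth = ArtificialCluster(
            center=(200.0, 90.0), r_km=20.0, rr=5, onset_month=10,
            C=0.02, p=0.1, n_t=500, n_c=500,
        )
        trt = sample_treatments(truth, zips, counties, seed=9)
        assert len(trt) == 500
        assert (np.abs(trt["x"] - 200.0) <= 20.0).all()
        assert (np.abs(trt["y"] - 90.0) <= 20.0).all()
        assert trt["month"].isin([10, 11, 12]).all()
        # window months near-uniform
        freq = trt["month"].value_counts(normalize=True)
        se = np.sqrt((1 / 3) * (2 / 3) / 500)
        assert (np.abs(freq - 1 / 3) < 4 * se).all()
        # unit ids assigned by the same nearest-seed rule as the pool
        assert np.array_equal(
            trt["zip_id"].to_numpy(), zips.assign(trt["x"], trt["y"])
        )


class TestAssembly:
    def test_thousand_records_with_stable_ids(self, small_study):
        pop, zips, counties = small_study
        ds = inject_dataset(pop, zips, counties, seed=21)
        assert ds.n == 1000
        assert ds.resolution == "address"
        assert np.array_equal(np.sort(ds.records["case_id"]), np.arange(1000))
        assert ds.records["is_treatment"].sum() == ds.truth.n_t
        trt = ds.records[ds.records["is_treatment"]]
        assert ds.truth.contains(trt["x"], trt["y"]).all()
        lo, hi = ds.truth.window
        assert trt["month"].between(lo, hi).all()

    def test_null_dataset_has_no_treatments(self, small_study):
        pop, zips, counties = small_study
        ds = inject_dataset(pop, zips, counties, seed=33, rr_values=[1])
        assert ds.truth.rr == 1 and ds.truth.p == 0.0 and ds.truth.n_t == 0
        assert not ds.records["is_treatment"].any()

    def test_injection_is_deterministic(self, small_study):
        pop, zips, counties = small_study
        a = inject_dataset(pop, zips, counties, seed=77)
        b = inject_dataset(pop, zips, counties, seed=77)
        assert a.truth == b.truth
        assert a.records.equals(b.records)

    def test_count_mismatch_rejected(self, small_study):
        pop, zips, counties = small_study
        truth = ArtificialCluster(
            center=(100.0, 90.0), r_km=10.0, rr=2, onset_month=0,
            C=0.01, p=0.02, n_t=20, n_c=980,
        )
        ctrl = sample_controls(pop, 979, seed=1)
        trt = sample_treatments(truth, zips, counties, seed=1)
        with pytest.raises(ValueError):
            assemble_dataset(ctrl, trt, truth, seed=1)


def test_realized_risk_recovery(small_study):
    """Generative-process oracle: for a fixed square, the mean
    observed/expected ratio inside recovers the injected RR within 5%
    wherever the target is attainable (no clamping)."""
    pop, _, _ = small_study
    center, r = (200.0, 120.0), 35.0
    C = compute_C(pop, center, r)
    assert 0.02 < C < 0.111  # keeps p < 1 up to RR = 9
    rng = np.random.default_rng(1234)
    inside = (np.abs(pop.x - center[0]) <= r) & (np.abs(pop.y - center[1]) <= r)
    for rr in (2, 5, 9):
        p, _ = compute_p(C, rr)
        assert p < 1.0, "chosen C,RR must not clamp"
        ratios = []
        for _ in range(200):
            n_t = rng.binomial(1000, p)
            idx = rng.choice(pop.n, size=1000 - n_t, replace=False)
            n_inside = n_t + int(inside[idx].sum())
            ratios.append(n_inside / (1000 * C))
        assert np.mean(ratios) == pytest.approx(rr, rel=0.05)
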