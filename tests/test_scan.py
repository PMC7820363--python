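"""Composite likelihoods, grid maximization and the scan surface."""

import math

import numpy as np
import pytest

from balscan import (
    BalancingScan,
    FootprintSpec,
    MixtureParams,
    ScanConfig,
    SiteRecord,
    SiteTable,
    alt_loglik,
    compute_B,
    default_A_grid,
    default_x_grid,
    inclusion_radius,
    neutral_dataset,
    normalize_background,
    null_loglik,
    scan,
    simplex_grid,
    synth_footprint,
)

from conftest import VARIANTS


def make_sites(ks, n=50, spacing=100, start=1000):
    phys = start + spacing * np.arange(len(ks))
    return SiteTable(phys, ks, np.full(len(ks), n), phys * 1e-6)


class TestComposedLikelihoods:
    def test_single_site_null(self, tiny_bg):
        g = normalize_background(tiny_bg, "2")
        sites = [SiteRecord(10, k=1, n=2)]
        assert null_loglik(sites, g) == pytest.approx(math.log(0.8), abs=1e-9)

    def test_product_rule_and_order_invariance(self, tiny_bg):
        g = normalize_background(tiny_bg, "2")
        s1 = [SiteRecord(10, 1, 2), SiteRecord(20, 1, 2)]
        assert null_loglik(s1, g) == pytest.approx(2 * math.log(0.8))
        s2 = [SiteRecord(5, 2, 2), SiteRecord(9, 1, 2), SiteRecord(2, 1, 2)]
        assert null_loglik(s2, g) == pytest.approx(null_loglik(s2[::-1], g))

    def test_empty_errors(self, g2):
        with pytest.raises(ValueError, match="no informative sites"):
            null_loglik([], g2)

    def test_zero_probability_cell_errors(self):
        from balscan import BackgroundSFS

        # background with no mass at k=2 for n=4
        bg = BackgroundSFS("derived", {(4, 1): 5, (4, 3): 5})
        g = normalize_background(bg, "2")
        with pytest.raises(ValueError, match="build the background"):
            null_loglik([SiteRecord(10, 2, 4)], g)

    def test_alt_equals_null_when_unlinked(self, g2):
        sites = [SiteRecord(int(p), k, 50) for p, k in [(1, 3), (2, 17), (3, 50)]]
        d = [5.0, 6.0, 7.0]  # alpha(1e4 * 5) ~ 0
        params = MixtureParams(A=1e4, x=0.5)
        assert alt_loglik(sites, d, params, g2) == pytest.approx(
            null_loglik(sites, g2), abs=1e-12
        )

    def test_fully_linked_single_site(self, tiny_bg):
        g = normalize_background(tiny_bg, "2")
        val = alt_loglik([SiteRecord(10, 1, 2)], [0.0], MixtureParams(A=5, x=0.5), g)
        assert val == pytest.approx(math.log(2 / 3), abs=1e-12)

    def test_alt_matches_naive_product_oracle(self, g2):
        rng = np.random.default_rng(11)
        n = 50
        ks = rng.integers(1, n + 1, size=100)
        sites = [SiteRecord(int(i), int(k), n) for i, k in enumerate(ks, 1)]
        d = rng.uniform(0, 0.01, size=100)
        params = MixtureParams(A=300.0, x=0.2)
        from balscan import balanced_component, linkage_weight

        expected = 0.0
        for s, di in zip(sites, d):
            a = linkage_weight(params.A, di)
            h = balanced_component(s.n, params.x, "2").prob(s.k)
            gk = float(g2.prob(s.n, s.k))
            expected += math.log(a * h + (1 - a) * gk if a >= 1e-8 else gk)
        got = alt_loglik(sites, d, params, g2)
        assert got == pytest.approx(expected, rel=1e-9)


class TestComputeB:
    def test_nestedness_on_neutral_data(self, g2):
        ds = neutral_dataset(300, g2, seed=7, n=50)
        rows = scan(ds, g2, ScanConfig(variant="2", test_site_policy=30))
        assert all(r.B >= 0 for r in rows)

    def test_null_optimal_gives_zero_and_sentinels(self, tiny_bg):
        # every site sits exactly at the background's modal composition
        g = normalize_background(tiny_bg, "2")
        ks = [1] * 8 + [2] * 2
        ds = make_sites(np.array(ks), n=2)
        row = compute_B(ds.phys_pos[5], ds, g, ScanConfig(variant="2"))
        assert row.B == 0.0
        assert math.isnan(row.x_hat) and math.isnan(row.A_hat)
        assert row.L_sites == 0

    def test_no_sites_in_window_gives_zero_row(self, g2):
        # at A=1e5 the inclusion radius is ~184 bp at 1e-6 cM/bp; a test
        # point midway between sites 1 kb apart sees no informative site
        ds = make_sites(np.array([5, 10]), spacing=1000, start=10**6)
        cfg = ScanConfig(variant="2", A_grid=[1e5])
        row = compute_B(10**6 + 500, ds, g2, cfg)
        assert row.B == 0.0 and row.L_sites == 0
        assert math.isnan(row.x_hat) and math.isnan(row.A_hat)

    def test_multiallelic_m2_reduces_to_biallelic(self, spectra):
        for variant in ("2", "2MAF"):
            g = spectra[variant]
            spec = FootprintSpec(x0=0.35, A0=500, n_sites=150, center=20000,
                                 site_spacing=50, seed=21)
            ds, _ = synth_footprint(spec, g)
            x_bi = list(default_x_grid(0.05))
            x_multi = simplex_grid(2, 0.05)
            a_grid = list(default_A_grid(10, 1e4, 6))
            r_bi = compute_B(20000, ds, g, ScanConfig(variant=variant, x_grid=x_bi, A_grid=a_grid))
            r_mu = compute_B(20000, ds, g, ScanConfig(variant=variant, m=2, x_grid=x_multi, A_grid=a_grid))
            assert r_mu.B == pytest.approx(r_bi.B, abs=1e-12)
            assert r_mu.A_hat == r_bi.A_hat

    def test_translation_invariance(self, g2):
        ds = neutral_dataset(100, g2, seed=3, n=50)
        shifted = SiteTable(ds.phys_pos + 10_000, ds.k, ds.n,
                            (ds.phys_pos + 10_000) * 1e-6)
        cfg = ScanConfig(variant="2")
        rows = scan(ds, g2, cfg)
        rows_shift = scan(shifted, g2, cfg)
        assert [r.B for r in rows] == pytest.approx([r.B for r in rows_shift], abs=1e-9)

    def test_locality_far_site_does_not_move_B(self, g2):
        ds = neutral_dataset(80, g2, seed=9, n=50)
        # append a site beyond the inclusion radius of the smallest A
        far_bp = int(inclusion_radius(1.0, 1e-8) / 1e-6) + int(ds.phys_pos[-1]) + 10**6
        aug = SiteTable(
            np.append(ds.phys_pos, far_bp),
            np.append(ds.k, 25),
            np.append(ds.n, 50),
            np.append(ds.gen_pos, far_bp * 1e-6),
        )
        cfg = ScanConfig(variant="2")
        r0 = compute_B(ds.phys_pos[40], ds, g2, cfg)
        r1 = compute_B(ds.phys_pos[40], aug, g2, cfg)
        assert r1.B == pytest.approx(r0.B, abs=1e-9)

    def test_window_radius_decreasing_in_A(self):
        radii = [inclusion_radius(A, 1e-8) for A in default_A_grid()]
        assert all(a > b for a, b in zip(radii, radii[1:]))


class TestScan:
    def test_policy_all(self, g2):
        ds = neutral_dataset(10, g2, seed=2, n=50)
        rows = scan(ds, g2, ScanConfig(variant="2"))
        assert len(rows) == 10
        assert [r.phys_pos for r in rows] == list(ds.phys_pos)

    def test_policy_every_second(self, g2):
        ds = neutral_dataset(10, g2, seed=2, n=50)
        rows = scan(ds, g2, ScanConfig(variant="2", test_site_policy=2))
        assert len(rows) == 5
        assert [r.phys_pos for r in rows] == list(ds.phys_pos[::2])

    def test_explicit_positions(self, g2):
        ds = neutral_dataset(10, g2, seed=2, n=50)
        pos = [int(ds.phys_pos[3]), int(ds.phys_pos[3]) + 7]
        rows = scan(ds, g2, ScanConfig(variant="2", test_site_policy=pos))
        assert [r.phys_pos for r in rows] == pos

    def test_scan_matches_independent_compute_B(self, g2):
        ds = neutral_dataset(40, g2, seed=4, n=50)
        cfg = ScanConfig(variant="2", test_site_policy=7)
        rows = scan(ds, g2, cfg)
        for r in rows:
            solo = compute_B(r.phys_pos, ds, g2, cfg)
            assert solo.B == pytest.approx(r.B, abs=0)
            assert solo.A_hat == r.A_hat or (math.isnan(solo.A_hat) and math.isnan(r.A_hat))

    def test_unsorted_and_duplicate_positions_error(self, g2):
        bad = SiteTable([10, 5], [1, 2], [50, 50])
        with pytest.raises(ValueError, match="sorted"):
            scan(bad, g2, ScanConfig(variant="2"))
        dup = SiteTable([10, 10], [1, 2], [50, 50])
        with pytest.raises(ValueError, match="duplicate"):
            scan(dup, g2, ScanConfig(variant="2"))


class TestModelResults:
    def test_fit_recovers_footprint(self, bg50, g2):
        spec = FootprintSpec(x0=0.3, A0=1000.0, n_sites=800, center=20000,
                             site_spacing=25, seed=5)
        ds, meta = synth_footprint(spec, g2)
        model = BalancingScan(ds.to_dataframe(), bg50, variant="2", test_site_policy=10)
        res = model.fit()
        peak = res.peak
        half_bp = math.log(2) / spec.A0 / spec.rate
        assert abs(peak.phys_pos - spec.center) <= half_bp
        assert abs(peak.x_hat - 0.3) <= 0.05
        assert meta["truth"]["x0"] == 0.3

    def test_summary_and_frame(self, bg50, g2):
        ds = neutral_dataset(50, g2, seed=12, n=50)
        res = BalancingScan(ds.to_dataframe(), bg50, variant="2", test_site_policy=10).fit()
        text = res.summary()
        assert "B2" in text and "max B" in text
        frame = res.frame
        assert list(frame.columns) == ["physPos", "genPos", "CLR", "x_hat", "A_hat", "n_sites"]
        assert len(frame) == 5

    def test_poly_only_variant_drops_substitutions(self, bg50):
        from balscan import normalize_background

        ds = neutral_dataset(100, normalize_background(bg50, "2"), seed=8, n=50)
        model = BalancingScan(ds.to_dataframe(), bg50, variant="0")
        n_subs = int(np.sum(ds.k == 50))
        assert model.n_dropped == n_subs
        assert len(model.data) == 100 - n_subs

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_scan_cleanly(self, variant, spectra):
        g = spectra[variant]
        ds = neutral_dataset(60, g, seed=15, n=50)
        rows = scan(ds, g, ScanConfig(variant=variant, test_site_policy=20))
        assert len(rows) == 3
        assert all(r.B >= 0 for r in rows)
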