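"""TE landscape: insertion ages, solo-LTR cascade, enrichment, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from panmosaic import te
from panmosaic.simulate import simulate_te_genome


class TestInsertionAge:
    def test_identical_ltrs_are_young(self):
        assert te.insertion_age(1.0) == 0.0

    def test_reference_rate_example(self):
        assert te.insertion_age(0.878, mu=6.1e-9) == pytest.approx(1.0e7)

    def test_linear_in_divergence_and_inverse_in_mu(self):
        t1 = te.insertion_age(0.9, mu=1e-8)
        assert te.insertion_age(0.95, mu=1e-8) == pytest.approx(t1 / 2)
        assert te.insertion_age(0.9, mu=2e-8) == pytest.approx(t1 / 2)

    def test_identity_bounds(self):
        with pytest.raises(ValueError):
            te.insertion_age(1.2)


def _ltr(chrom="chr1", start=10_000, length=400, name="famA", method="homology",
         identity=0.9, score=500.0, role="long_terminal_repeat", element_id=None,
         superfamily="Ty1/Copia"):
    return te.TERecord(chrom=chrom, start=start, end=start + length, strand="+",
                       superfamily=superfamily, role=role, method=method, name=name,
                       element_id=element_id, identity=identity, score=score)


class TestSoloLtrCascade:
    def test_short_record_fails_length_filter(self):
        calls = te.identify_solo_ltrs([_ltr(length=90)])
        assert not calls[0].passed
        assert calls[0].audit["min_length"] is False

    def test_part_of_intact_element_is_not_a_candidate(self):
        intact = _ltr(start=1_000, role="intact_element", method="structural",
                      element_id="e1")
        part = _ltr(start=1_000, method="homology", element_id="e1")
        calls = te.identify_solo_ltrs([intact, part])
        assert calls == []

    def test_identity_and_score_thresholds(self):
        calls = te.identify_solo_ltrs([
            _ltr(start=10_000, identity=0.75),
            _ltr(start=30_000, score=250.0, name="famB"),
            _ltr(start=50_000, name="famC"),
        ])
        by_start = {c.record.start: c for c in calls}
        assert by_start[10_000].audit["min_identity"] is False
        assert by_start[30_000].audit["min_score"] is False
        assert by_start[50_000].passed

    def test_same_family_neighbor_fails(self):
        calls = te.identify_solo_ltrs([
            _ltr(start=10_000, name="famX"),
            _ltr(start=20_000, name="famX"),
            _ltr(start=40_000, name="famY"),
        ])
        by_start = {c.record.start: c for c in calls}
        assert by_start[10_000].audit["neighbor_id"] is False
        assert by_start[20_000].audit["neighbor_id"] is False
        assert by_start[40_000].passed

    def test_close_candidates_fail_distance(self):
        calls = te.identify_solo_ltrs([
            _ltr(start=10_000, name="famA"),
            _ltr(start=13_000, name="famB"),
        ])
        assert all(c.audit["min_distance"] is False for c in calls)

    def test_percentile_filter_skipped_without_structural_ltrs(self):
        with pytest.warns(UserWarning, match="percentile"):
            calls = te.identify_solo_ltrs([_ltr()])
        assert calls[0].audit["max_length_p95"] is None
        assert calls[0].passed

    def test_oversized_solo_fails_percentile(self):
        structural = [
            _ltr(start=100_000 + 10_000 * i, length=300, method="structural",
                 name=f"s{i}", element_id=None)
            for i in range(10)
        ]
        big = _ltr(start=10_000, length=2_000)
        calls = te.identify_solo_ltrs([big] + structural)
        assert calls[0].audit["max_length_p95"] is False

    def test_synthetic_genome_truth_recovery(self):
        _, records, bundle = simulate_te_genome(n_intact=3, n_solo=5, seed=17)
        calls = te.identify_solo_ltrs(records)
        truth = bundle.truth["features"]
        expected = set(truth[truth.should_pass].start)
        called = {c.record.start for c in calls if c.passed}
        assert called == expected
        intact = [(r.start, r.end) for r in records if r.role == "intact_element"]
        for c in calls:
            if c.passed:
                assert not any(c.record.start < e and c.record.end > s
                               for s, e in intact)


class TestSoloIntactRatio:
    def test_simple_ratio(self):
        records = [
            _ltr(start=100_000 + 20_000 * i, role="intact_element",
                 method="structural", element_id=f"e{i}")
            for i in range(3)
        ]
        calls = te.identify_solo_ltrs(
            records
            + [_ltr(start=10_000 * (i + 1) + 400_000, name=f"f{i}") for i in range(6)]
        )
        table = te.solo_intact_ratio(calls, records)
        row = table[table.superfamily == "Ty1/Copia"].iloc[0]
        assert row.ratio == pytest.approx(2.0)

    def test_zero_intact_is_missing_not_infinite(self):
        calls = te.identify_solo_ltrs([_ltr()])
        table = te.solo_intact_ratio(calls, [])
        assert np.isnan(table.iloc[0].ratio)

    def test_zero_solos_is_zero(self):
        intact = _ltr(role="intact_element", method="structural", element_id="e1")
        table = te.solo_intact_ratio([], [intact])
        assert table.iloc[0].ratio == 0.0


class TestFlankIntervals:
    def test_both_sides(self):
        out = te.flank_intervals([("chr1", 5_000, 6_000)], 1_000, {"chr1": 100_000})
        assert [(c, s, e) for c, s, e, *_ in out] == [
            ("chr1", 4_000, 5_000),
            ("chr1", 6_000, 7_000),
        ]

    def test_truncation_at_chromosome_start(self):
        out = te.flank_intervals([("chr1", 0, 500)], 1_000, {"chr1": 10_000})
        assert [(s, e, side) for _, s, e, _, side in out] == [(500, 1_500, "downstream")]

    def test_nonpositive_flank_rejected(self):
        with pytest.raises(ValueError):
            te.flank_intervals([("chr1", 10, 20)], 0, {"chr1": 100})

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_flanks_never_overlap_feature_body(self, seed):
        rng = np.random.default_rng(seed)
        feats = []
        for _ in range(10):
            s = int(rng.integers(0, 90_000))
            feats.append(("chr1", s, s + int(rng.integers(1, 5_000))))
        for chrom, s, e, idx, _ in te.flank_intervals(
            [(c, s, min(e, 100_000)) for c, s, e in feats], 1_000, {"chr1": 100_000}
        ):
            fs, fe = feats[idx][1], min(feats[idx][2], 100_000)
            assert e <= fs or s >= fe


class TestEnrichment:
    def test_equal_proportions_give_unit_score(self):
        res = te.te_enrichment_test([("t", "f", 10, 100, 100, 1000)])
        assert res[0].es == pytest.approx(1.0)

    def test_doubled_proportion(self):
        res = te.te_enrichment_test([("t", "f", 20, 100, 100, 1000)])
        assert res[0].es == pytest.approx(2.0)

    def test_point_probability_matches_exhaustive_margin_enumeration(self):
        a, b, c, d = 3, 2, 4, 5
        # enumerate all tables with the same margins; the point probability is
        # the multivariate-hypergeometric weight of the observed table
        n = a + b + c + d
        r1, c1 = a + b, a + c
        weights = {}
        from math import comb

        for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            weights[aa] = comb(r1, aa) * comb(n - r1, c1 - aa)
        expected = weights[a] / sum(weights.values())
        assert te.fisher_point_probability(a, b, c, d) == pytest.approx(
            expected, rel=1e-12
        )

    def test_point_probability_matches_hypergeometric_pmf(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            p = te.fisher_point_probability(a, b, c, d)
            expected = hypergeom.pmf(a, a + b + c + d, a + b, a + c)
            assert p == pytest.approx(expected, rel=1e-9, abs=1e-300)

    def test_es_scale_invariance(self):
        r1 = te.te_enrichment_test([("t", "f", 5, 50, 40, 400)])[0].es
        r2 = te.te_enrichment_test([("t", "f", 15, 150, 120, 1200)])[0].es
        assert r1 == pytest.approx(r2)

    def test_zero_c_is_missing(self):
        res = te.te_enrichment_test([("t", "f", 0, 10, 0, 100)])
        assert np.isnan(res[0].es)

    def test_bh_monotone_and_null_safe(self):
        tables = [("t", str(i), 1, 10, 10, 100) for i in range(4)]
        res = te.te_enrichment_test(tables)
        ps = [r.p for r in res]
        qs = [r.q for r in res]
        order = np.argsort(ps)
        assert (np.diff(np.array(qs)[order]) >= -1e-12).all()
        # with all p = 1 nothing is significant
        flat = te.te_enrichment_test([("t", "f", 0, 1, 0, 1)] * 3)
        assert not any(r.significant for r in flat)


class TestGeneTeDistances:
    def test_gap_and_overlap(self):
        tes = [_ltr(start=300, length=100, role="fragment")]
        out = te.gene_te_distances([("chr1", 100, 200, "g1")], tes)
        assert out.iloc[0].distance == 100
        out = te.gene_te_distances([("chr1", 250, 350, "g2")], tes)
        assert out.iloc[0].distance == 0

    def test_chromosome_without_tes_is_missing(self):
        tes = [_ltr(chrom="chr2", role="fragment")]
        out = te.gene_te_distances([("chr1", 0, 10, "g1")], tes)
        assert np.isnan(out.iloc[0].distance)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        tes = []
        for i in range(100):
            s = int(rng.integers(0, 500_000))
            tes.append(_ltr(start=s, length=int(rng.integers(100, 2_000)),
                            role="fragment", name=f"t{i}",
                            superfamily=["Ty1/Copia", "Helitron"][i % 2]))
        genes = []
        for i in range(100):
            s = int(rng.integers(0, 500_000))
            genes.append(("chr1", s, s + int(rng.integers(200, 3_000)), f"g{i}"))
        out = te.gene_te_distances(genes, tes)
        for _, row in out.iterrows():
            gs, ge = next((s, e) for c, s, e, g in genes if g == row.gene_id)
            dists = [
                max(t.start - ge, gs - t.end, 0)
                for t in tes
                if t.superfamily == row.category
            ]
            assert row.distance == min(dists)
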