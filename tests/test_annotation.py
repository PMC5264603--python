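"""Interval arithmetic on the shipped catalogue, the strict novelty rule,
gene overlap against a brute-force scan, recurrence counting, cohort
summaries, and the enrichment statistics against enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvpipe.annotate import (
    annotate_genes,
    bh_fdr,
    classify_novelty,
    hypergeom_enrich,
    interval_length,
    overlap_fraction,
    recurrence,
    recurrent_fraction_pct,
    summarize_cohort,
)
from cnvpipe.array_io import Region, RegionIndex
from cnvpipe.catalogue import (
    ALL_CATALOGUE,
    COHORT_RECURRENT_CNVS,
    COHORT_TOTAL_CNVS,
    DISCREPANT_ENTRY,
)
from cnvpipe.core import CnvCall, GenomicInterval


def call(start, end, state="gain", patient="p1", chrom="chr1"):
    return CnvCall(
        interval=GenomicInterval(chrom, start, end),
        state=state,
        n_probes=5,
        mean_log2=1.2 if state == "gain" else -1.2,
        patient_id=patient,
    )


class TestIntervalArithmetic:
    @pytest.mark.parametrize(
        "start,end,length",
        [
            (89474710, 89479067, 4358),
            (242865920, 243076752, 210833),
            (101911972, 101944947, 32976),
            (109547804, 109661604, 113801),
            (57734690, 64120329, 6385640),
            (90703280, 92347529, 1644250),
            (26038217, 27819206, 1780990),
            (5, 5, 1),
        ],
    )
    def test_printed_lengths_reproduced(self, start, end, length):
        assert interval_length(GenomicInterval("x", start, end)) == length

    def test_catalogue_lengths_match_except_documented_typo(self):
        mismatched = [
            e for e in ALL_CATALOGUE if e.derived_length_bp != e.printed_length_bp
        ]
        assert mismatched == [DISCREPANT_ENTRY]
        assert DISCREPANT_ENTRY.printed_length_bp - DISCREPANT_ENTRY.derived_length_bp == 40


class TestOverlapFraction:
    def test_identical(self):
        a = GenomicInterval("chr1", 100, 199)
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint_and_cross_chromosome(self):
        a = GenomicInterval("chr1", 100, 199)
        assert overlap_fraction(a, GenomicInterval("chr1", 300, 400)) == 0.0
        assert overlap_fraction(a, GenomicInterval("chr2", 100, 199)) == 0.0

    def test_half_overlap_hand_computed(self):
        a = GenomicInterval("chr1", 100, 199)
        b = GenomicInterval("chr1", 150, 299)
        assert overlap_fraction(a, b) == pytest.approx(0.5)
        assert overlap_fraction(b, a) == pytest.approx(50 / 150)
        assert overlap_fraction(a, b, reciprocal=True) == pytest.approx(50 / 150)


class TestNovelty:
    def db(self, *intervals):
        return RegionIndex([Region(iv, f"r{i}") for i, iv in enumerate(intervals)])

    def test_fully_covered_is_known(self):
        db = self.db(GenomicInterval("chr1", 1, 10_000))
        assert classify_novelty(call(2000, 3000), db) == "known"

    def test_boundary_cases_around_half(self):
        """Strict 'more than 50%': 0.49 and exactly 0.50 stay novel, 0.51
        is known."""
        a = call(1, 100)
        assert classify_novelty(a, self.db(GenomicInterval("chr1", 52, 100))) == "novel"  # 0.49
        assert classify_novelty(a, self.db(GenomicInterval("chr1", 51, 100))) == "novel"  # 0.50
        assert classify_novelty(a, self.db(GenomicInterval("chr1", 50, 100))) == "known"  # 0.51

    def test_empty_db_everything_novel(self):
        assert classify_novelty(call(1, 100), self.db()) == "novel"


class TestGenes:
    def test_contained_gene_annotated(self):
        genes = RegionIndex([Region(GenomicInterval("chr1", 2000, 2500), "GENE1")])
        assert annotate_genes(call(1000, 3000), genes) == ["GENE1"]

    def test_gene_desert_empty(self):
        genes = RegionIndex([Region(GenomicInterval("chr2", 1, 100), "FAR")])
        assert annotate_genes(call(1000, 3000), genes) == []

    def test_agreement_with_brute_force(self):
        rng = np.random.default_rng(77)
        regions = []
        for i in range(400):
            s = int(rng.integers(1, 10**6))
            regions.append(Region(GenomicInterval("chr1", s, s + int(rng.integers(1, 3000))), f"G{i}"))
        genes = RegionIndex(regions)
        for _ in range(1000):
            s = int(rng.integers(1, 10**6))
            c = GenomicInterval("chr1", s, s + int(rng.integers(0, 5000)))
            expected = [r.name for r in sorted(regions, key=lambda r: r.interval.start)
                        if r.interval.overlaps(c)]
            assert annotate_genes(c, genes) == expected


class TestRecurrence:
    def test_single_patient_not_recurrent(self):
        df = recurrence({"p1": [call(1, 100), call(500, 600)]})
        assert (df["n_patients"] == 1).all()
        assert not df["recurrent"].any()

    def test_shared_locus_counted_across_patients(self):
        calls = {
            f"p{i}": [call(10_000, 20_000, patient=f"p{i}")] for i in range(1, 8)
        }
        calls["p8"] = [call(900_000, 950_000, patient="p8")]
        df = recurrence(calls)
        shared = df[df["start"] == 10_000]
        assert (shared["n_patients"] == 7).all()
        assert not df[df["start"] == 900_000]["recurrent"].iloc[0]

    def test_low_reciprocal_overlap_not_matched(self):
        df = recurrence({
            "p1": [call(1, 1000, patient="p1")],
            "p2": [call(900, 10_000, patient="p2")],
        })
        assert not df["recurrent"].any()

    def test_printed_recurrence_percentage(self):
        assert recurrent_fraction_pct(COHORT_RECURRENT_CNVS, COHORT_TOTAL_CNVS) == 61


class TestSummary:
    def test_hand_computed_fixture(self):
        calls = {
            "p1": [call(1, 1000), call(10_000, 11_999, state="loss")],
            "p2": [call(1, 1000, patient="p2"), call(50_000, 50_499, state="loss", patient="p2")],
        }
        s = summarize_cohort(calls)
        assert s.total_cnvs == 4
        assert s.per_patient_mean == 2.0
        assert s.per_patient_min == 2 and s.per_patient_max == 2
        assert s.size_min_bp == 500 and s.size_max_bp == 2000
        assert s.size_mean_bp == pytest.approx((1000 + 2000 + 1000 + 500) / 4)
        assert s.loss_fraction == pytest.approx(0.5)
        assert s.recurrent_count == 2  # the locus shared by p1 and p2
        assert s.recurrent_fraction == pytest.approx(0.5)

    def test_all_gains_zero_loss_fraction(self):
        s = summarize_cohort({"p1": [call(1, 100), call(500, 700)]})
        assert s.loss_fraction == 0.0

    def test_empty_cohort_flagged(self):
        s = summarize_cohort({"p1": []})
        assert s.empty and s.total_cnvs == 0

    def test_genic_fraction(self):
        genes = RegionIndex([Region(GenomicInterval("chr1", 1, 2000), "G")])
        s = summarize_cohort({"p1": [call(1, 100), call(600_000, 700_000)]}, genes=genes)
        assert s.genic_count == 1
        assert s.genic_fraction == pytest.approx(0.5)


def enumeration_hypergeom(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets."""
    universe = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestEnrichment:
    def test_closed_form_example(self):
        # N=10, K=5, n=3, k=3: C(5,3)/C(10,3) = 10/120
        universe = [f"g{i}" for i in range(10)]
        p = hypergeom_enrich(universe[:3], universe[:5], universe)
        assert p == pytest.approx(10 / 120)

    def test_zero_hits_give_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        p = hypergeom_enrich(universe[5:8], universe[:3], universe)
        assert 0 < p <= 1.0
        assert hypergeom_enrich([], universe[:3], universe) == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], ["g0"], ["g0", "g1"])

    def test_matches_enumeration_for_all_small_instances(self):
        """Agreement with the subset-enumeration oracle for every
        configuration with N <= 12."""
        for N in range(1, 13):
            universe = [f"g{i}" for i in range(N)]
            for K in range(N + 1):
                for n in range(N + 1):
                    p = hypergeom_enrich(universe[:n], universe[:K], universe)
                    k = min(n, K)
                    expected = enumeration_hypergeom(N, K, n, k)
                    assert p == pytest.approx(expected, abs=1e-12), (N, K, n)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_example_all_ties(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        q = bh_fdr(p)
        assert bh_fdr(q) == pytest.approx(q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_sorted_qvalues_monotone(self, pvals):
        """Sorting by p sorts q: the step-up correction preserves order."""
        q = bh_fdr(pvals)
        order = np.argsort(pvals, kind="stable")
        q_sorted = q[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)
        assert np.all((q >= np.asarray(pvals) - 1e-12) & (q <= 1.0 + 1e-12))
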