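import itertools

import numpy as np
import pytest

from metaclone.clonality import (
    estimate_multiplicity,
    expected_vaf,
    summarize_gene_hits,
    vaf_cn_table,
)
from metaclone.io_formats import CopyNumberSegment, SegmentIndex

from conftest import make_variant


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "m, cn, purity, expected",
        [
            (1, 2, 1.0, 0.5),  # heterozygous diploid
            (1, 3, 1.0, 1 / 3),  # single copy in a trisomic region (VAF ~30%)
            (2, 3, 1.0, 2 / 3),  # two of three copies (VAF ~55-65%)
            (1, 1, 1.0, 1.0),  # hemizygous pure tumour
            (1, 1, 0.8, 0.8 / 1.2),  # hemizygous at 80% purity
        ],
    )
    def test_worked_values(self, m, cn, purity, expected):
        assert expected_vaf(m, cn, purity) == pytest.approx(expected)

    def test_purity_one_reduces_to_m_over_cn(self):
        for cn in range(1, 5):
            for m in range(1, cn + 1):
                assert expected_vaf(m, cn, 1.0) == pytest.approx(m / cn)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_vaf(3, 2, 1.0)
        with pytest.raises(ValueError):
            expected_vaf(1, 0, 1.0)
        with pytest.raises(ValueError):
            expected_vaf(1, 2, 0.0)

    def test_strictly_increasing_in_m_and_purity(self):
        for cn in range(1, 5):
            for rho in (0.3, 0.6, 0.8, 1.0):
                vals = [expected_vaf(m, cn, rho) for m in range(1, cn + 1)]
                assert all(b > a for a, b in zip(vals, vals[1:]))
        for m, cn in [(1, 2), (2, 3), (1, 4)]:
            vals = [expected_vaf(m, cn, rho) for rho in np.linspace(0.1, 1.0, 10)]
            assert all(b > a for a, b in zip(vals, vals[1:]))


KEY = ("chr13", 100, "G", "A")


class TestEstimateMultiplicity:
    def test_trisomic_single_copy_clonal(self):
        call = estimate_multiplicity(KEY, "M1", 0.30, total_cn=3, purity=1.0)
        assert call.m_hat == 1 and call.clonal_flag and not call.superclonal_flag

    def test_trisomic_two_copies(self):
        # 0.55 and 0.65 are both nearest the two-copy expectation 2/3;
        # only 0.65 sits within the clonal tolerance of it
        for vaf in (0.55, 0.65):
            call = estimate_multiplicity(KEY, "M1", vaf, total_cn=3, purity=1.0)
            assert call.m_hat == 2
        assert estimate_multiplicity(KEY, "M1", 0.65, 3, 1.0).clonal_flag

    def test_subclonal_low_vaf(self):
        call = estimate_multiplicity(KEY, "M1", 0.12, total_cn=2, purity=1.0)
        assert call.m_hat == 1 and not call.clonal_flag and not call.superclonal_flag

    def test_superclonal_flag_follows_purity(self):
        # VAF 0.80 at hemizygous CN: consistent at purity 1 (expected 1.0),
        # impossible at purity 0.8 where even m = cn expects only 0.667
        pure = estimate_multiplicity(KEY, "M1", 0.80, total_cn=1, purity=1.0)
        assert pure.m_hat == 1 and not pure.superclonal_flag
        impure = estimate_multiplicity(KEY, "M1", 0.80, total_cn=1, purity=0.8)
        assert impure.superclonal_flag

    def test_tie_broken_toward_smaller_m(self):
        # midpoint between expected VAFs 0.25 and 0.50 at cn=4
        call = estimate_multiplicity(KEY, "M1", 0.375, total_cn=4, purity=1.0)
        assert call.m_hat == 1

    def test_expected_mapping_strictly_increasing(self):
        call = estimate_multiplicity(KEY, "M1", 0.4, total_cn=4, purity=0.7)
        vals = [call.expected_vaf_by_m[m] for m in range(1, 5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_recovery_from_binomial_sampling(self):
        rng = np.random.default_rng(5)
        hits = total = 0
        for cn in range(1, 5):
            for m in range(1, cn + 1):
                for rho in (0.6, 0.8, 1.0):
                    p = expected_vaf(m, cn, rho)
                    for vaf in rng.binomial(1000, p, size=50) / 1000:
                        call = estimate_multiplicity(KEY, "M1", float(vaf), cn, rho)
                        hits += call.m_hat == m
                        total += 1
        assert hits / total >= 0.99


def _seg_index(cn_by_interval):
    segs = [
        CopyNumberSegment("M1", chrom, s, e, cn) for chrom, s, e, cn in cn_by_interval
    ]
    return SegmentIndex(segs)


class TestGeneHitSummary:
    def test_three_allele_inactivation(self):
        """Two hits at VAFs 0.30 / 0.55 in a CN-3 region imply multiplicities
        1 + 2 = all three alleles inactivated."""
        index = _seg_index([("chr13", 0, 10_000, 3)])
        hits = [
            make_variant(chrom="chr13", pos=100, ref="G", alt="A", vaf=0.30, gene="RB1",
                         effect="nonsense"),
            make_variant(chrom="chr13", pos=900, ref="C", alt="T", vaf=0.55, gene="RB1",
                         effect="splice_site"),
        ]
        s = summarize_gene_hits(hits, index)
        assert [c.m_hat for c in s.hits] == [1, 2]
        assert s.inferred_inactivated_alleles == 3
        assert s.biallelic_flag and not s.mixed_cn_flag

    def test_single_het_hit_not_biallelic(self):
        index = _seg_index([("chr1", 0, 10_000, 2)])
        s = summarize_gene_hits(
            [make_variant(vaf=0.5, gene="PTEN", effect="nonsense")], index
        )
        assert s.inferred_inactivated_alleles == 1 and not s.biallelic_flag

    def test_two_het_hits_biallelic(self):
        index = _seg_index([("chr1", 0, 10_000, 2)])
        hits = [
            make_variant(pos=100, vaf=0.5, gene="PTEN", effect="nonsense"),
            make_variant(pos=200, ref="G", alt="A", vaf=0.5, gene="PTEN", effect="frameshift"),
        ]
        s = summarize_gene_hits(hits, index)
        assert s.inferred_inactivated_alleles == 2 and s.biallelic_flag

    def test_non_inactivating_hits_do_not_count(self):
        index = _seg_index([("chr1", 0, 10_000, 2)])
        hits = [
            make_variant(pos=100, vaf=0.5, gene="PTEN", effect="missense"),
            make_variant(pos=200, ref="G", alt="A", vaf=0.5, gene="PTEN", effect="nonsense"),
        ]
        s = summarize_gene_hits(hits, index)
        assert s.inferred_inactivated_alleles == 1

    def test_mixed_cn_flagged(self):
        index = _seg_index([("chr1", 0, 500, 2), ("chr1", 500, 10_000, 3)])
        hits = [
            make_variant(pos=100, vaf=0.5, gene="G", effect="nonsense"),
            make_variant(pos=600, ref="G", alt="A", vaf=0.33, gene="G", effect="nonsense"),
        ]
        s = summarize_gene_hits(hits, index)
        assert s.mixed_cn_flag and s.total_cn == 3

    def test_matches_exhaustive_enumeration(self):
        """Per-hit argmin equals the joint assignment minimizing total
        absolute VAF error (the objective is separable)."""
        rng = np.random.default_rng(9)
        index = _seg_index([("chr1", 0, 100_000, 3)])
        for _ in range(50):
            vafs = rng.uniform(0.05, 1.0, size=int(rng.integers(1, 4)))
            hits = [
                make_variant(pos=100 + 10 * i, vaf=round(float(v), 2), gene="G",
                             effect="nonsense")
                for i, v in enumerate(vafs)
            ]
            s = summarize_gene_hits(hits, index)
            best = min(
                itertools.product(range(1, 4), repeat=len(hits)),
                key=lambda ms: sum(
                    abs(h.vaf - expected_vaf(m, 3, 1.0)) for h, m in zip(hits, ms)
                ),
            )
            assert s.inferred_inactivated_alleles == sum(best)


class TestVafCnTable:
    def test_uncovered_site_flagged(self, patient1_cohort):
        from metaclone.partition import partition_patient

        c = patient1_cohort
        lesions = c.lesions_of(c.patients[0])
        patterns, _ = partition_patient(c.variants, lesions, depth_lookup=c.site_depths)
        index = SegmentIndex([])  # no coverage at all
        df = vaf_cn_table(patterns, c.variants, index)
        assert df["cn_missing"].all()
        assert df["total_cn"].isna().all()

    def test_truncal_diploid_vafs_near_half(self, patient1_cohort):
        from metaclone.partition import partition_patient

        c = patient1_cohort
        lesions = c.lesions_of(c.patients[0])
        patterns, _ = partition_patient(c.variants, lesions, depth_lookup=c.site_depths)
        df = vaf_cn_table(patterns, c.variants, SegmentIndex(c.segments))
        shared_diploid = df[(df.category == "truncal") & (df.total_cn == 2)]
        assert 0.45 <= shared_diploid.vaf.mean() <= 0.55
        assert set(df.category.unique()) <= {"truncal", "shared_subset", "private"}

    def test_empty_input(self):
        df = vaf_cn_table([], [], SegmentIndex([]))
        assert df.empty
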