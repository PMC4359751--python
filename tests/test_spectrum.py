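import numpy as np
import pytest

from metaclone.spectrum import (
    PAIR_CLASSES,
    classify_substitution,
    revcomp,
    sample_coding_AT_sites,
    spectrum_profile,
    window_context_test,
)

from conftest import make_variant

ALL_SUBS = [
    ("C", "T", "C:G>T:A"),
    ("G", "A", "C:G>T:A"),
    ("C", "A", "C:G>A:T"),
    ("G", "T", "C:G>A:T"),
    ("C", "G", "C:G>G:C"),
    ("G", "C", "C:G>G:C"),
    ("T", "C", "A:T>G:C"),
    ("A", "G", "A:T>G:C"),
    ("T", "A", "A:T>T:A"),
    ("A", "T", "A:T>T:A"),
    ("T", "G", "A:T>C:G"),
    ("A", "C", "A:T>C:G"),
]


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref, alt, expected", ALL_SUBS)
    def test_all_twelve_substitutions(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    @pytest.mark.parametrize("ref, alt, _", ALL_SUBS)
    def test_strand_symmetry(self, ref, alt, _):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert classify_substitution(ref, alt) == classify_substitution(comp[ref], comp[alt])

    def test_indels_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("CA", "C")
        with pytest.raises(ValueError):
            classify_substitution("C", "C")


class TestSpectrumProfile:
    def test_class_fractions(self):
        ref = {"chr1": "TC" * 50 + "AT" * 50}
        variants = [
            make_variant(pos=2 * i + 2, ref="C", alt="T") for i in range(9)
        ] + [make_variant(pos=102, ref="T", alt="A")]
        prof = spectrum_profile(variants, ref)
        assert prof.n_total == 10
        assert prof.fractions["C:G>T:A"] == pytest.approx(0.9)
        assert prof.fractions["A:T>T:A"] == pytest.approx(0.1)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_all_TC_context_gives_full_5prime_pyrimidine_fraction(self):
        ref = {"chr1": "TC" * 50}  # every C preceded by T
        variants = [make_variant(pos=2 * i + 2, ref="C", alt="T") for i in range(20)]
        prof = spectrum_profile(variants, ref)
        assert prof.five_prime_pyrimidine_fraction == 1.0

    def test_G_ref_reads_flank_on_opposite_strand(self):
        # plus strand ...GA...: mutated G, pyrimidine strand has C preceded
        # by complement of the base 3' of G (A -> T, a pyrimidine)
        ref = {"chr1": "TTGATT"}
        prof = spectrum_profile([make_variant(pos=3, ref="G", alt="A")], ref)
        assert prof.counts["C:G>T:A"] == 1
        assert prof.five_prime_pyrimidine_fraction == 1.0

    def test_reference_mismatch_dropped_and_hard_error_over_threshold(self):
        ref = {"chr1": "A" * 100}
        ok = make_variant(pos=1, ref="A", alt="G")
        bad = [make_variant(pos=i, ref="C", alt="T") for i in range(2, 8)]
        with pytest.raises(ValueError, match="genome build"):
            spectrum_profile([ok] + bad, ref)
        prof = spectrum_profile([ok] * 19 + bad[:1], ref)
        assert prof.n_ref_mismatch == 1 and prof.n_total == 19

    def test_planted_uv_fraction_recovered(self):
        """Median per-patient C:G>T:A fraction across simulated patients
        stays within 0.05 of the planted probability."""
        from metaclone.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(
            n_patients=20,
            lesions_per_patient=2,
            n_truncal=30,
            n_subset_shared=0,
            n_private=(2, 2),
            private_signatures=("UV", "UV"),
        )
        cohort = simulate_cohort(cfg, seed=23)
        truth = cohort.truth.category_of()
        fractions = []
        for pid in cohort.patients:
            lesions = cohort.lesions_of(pid)
            shared = [
                v
                for v in cohort.variants
                if v.lesion_id == lesions[0] and truth[v.key] == "truncal"
            ]
            prof = spectrum_profile(shared, cohort.reference)
            fractions.append(prof.fractions["C:G>T:A"])
        assert abs(np.median(fractions) - cfg.uv_p_cgta) <= 0.05

    def test_planted_5prime_pyrimidine_recovered_at_large_n(self):
        from metaclone.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(
            n_patients=1,
            lesions_per_patient=2,
            n_truncal=500,
            n_subset_shared=0,
            n_private=(0, 0),
        )
        cohort = simulate_cohort(cfg, seed=29)
        lesions = cohort.lesions_of(cohort.patients[0])
        mine = [v for v in cohort.variants if v.lesion_id == lesions[0]]
        prof = spectrum_profile(mine, cohort.reference)
        assert prof.five_prime_pyrimidine_fraction == pytest.approx(
            cfg.uv_p_5prime_pyrimidine, abs=0.04
        )


class TestSampleCodingATSites:
    def test_exhaustive_tiny_region(self):
        ref = {"chr1": "AAAA"}
        sites = sample_coding_AT_sites(ref, [("chr1", 0, 4)], n=4, rng=np.random.default_rng(0))
        assert sorted(p for _, p, _ in sites) == [1, 2, 3, 4]
        assert all(b == "A" for _, _, b in sites)

    def test_same_seed_reproducible(self, toy_reference):
        intervals = [("chr1", 0, 2000)]
        a = sample_coding_AT_sites(toy_reference, intervals, 50, np.random.default_rng(3))
        b = sample_coding_AT_sites(toy_reference, intervals, 50, np.random.default_rng(3))
        assert a == b

    def test_insufficient_sites_rejected(self):
        with pytest.raises(ValueError, match="A/T sites"):
            sample_coding_AT_sites({"chr1": "GCGC"}, [("chr1", 0, 4)], n=1)

    def test_near_uniform_inclusion(self, toy_reference):
        intervals = [("chr1", 0, 500)]
        counts: dict[int, int] = {}
        rng = np.random.default_rng(31)
        n_at = sum(b in "AT" for b in toy_reference["chr1"][:500])
        for _ in range(400):
            for _, p, _ in sample_coding_AT_sites(toy_reference, intervals, 20, rng):
                counts[p] = counts.get(p, 0) + 1
        freqs = np.array(list(counts.values())) / 400
        assert len(counts) == n_at  # every A/T site eventually drawn
        assert abs(freqs.mean() - 20 / n_at) < 0.01


def _forced_context_reference(n_mut=30, n_rand=200, p_g=0.9, seed=5):
    """Toy genome whose mutated sites carry G at +1 with probability p_g
    while background sites are uniform."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = list(bases[i] for i in rng.integers(0, 4, size=20_000))
    mut_sites, rand_sites = [], []
    pos = 50
    for i in range(n_mut + n_rand):
        seq[pos] = "A"
        if i < n_mut and rng.random() < p_g:
            seq[pos + 1] = "G"
        (mut_sites if i < n_mut else rand_sites).append(("chr1", pos + 1))
        pos += 40
    return {"chr1": "".join(seq)}, mut_sites, rand_sites


class TestWindowContextTest:
    def test_identical_site_lists_give_p_one(self, toy_reference):
        sites = [
            ("chr1", i + 1)
            for i, b in enumerate(toy_reference["chr1"][:500])
            if b in "AT"
        ][:30]
        res = window_context_test(sites, sites, toy_reference, k=3,
                                  n_permutations=2000, rng=np.random.default_rng(0))
        assert np.all(res.raw_p == 1.0) and np.all(res.adjusted_p == 1.0)

    def test_forced_plus1_bias_detected(self):
        ref, mut, rand = _forced_context_reference()
        res = window_context_test(mut, rand, ref, k=5, n_permutations=20_000,
                                  rng=np.random.default_rng(1))
        assert res.p_at(1) < 0.01  # adjusted
        assert res.p_at(-5, adjusted=False) > 0.01 or res.p_at(-5) > res.p_at(1)

    def test_adjusted_never_below_raw_and_composition_margins(self):
        ref, mut, rand = _forced_context_reference()
        res = window_context_test(mut, rand, ref, k=4, n_permutations=5000,
                                  rng=np.random.default_rng(2))
        assert np.all(res.adjusted_p >= res.raw_p)
        assert (res.mutated_composition.sum(axis=1) == res.n_mutated).all()
        assert (res.random_composition.sum(axis=1) == res.n_random).all()

    def test_T_centre_windows_reverse_complemented(self):
        # A-strand orientation: a T site's +1 is the base 5' on the
        # reference, complemented
        ref = {"chr1": "AAAA" + "CTAA" * 30 + "A" * 20}
        mut = [("chr1", 6 + 4 * i) for i in range(20)]  # T sites, 5' neighbour C
        rand = [("chr1", 7 + 4 * i) for i in range(20)]  # A sites, +1 = A
        res = window_context_test(mut, rand, ref, k=2, n_permutations=2000,
                                  rng=np.random.default_rng(3))
        i = res.positions.index(1)
        g = res.mutated_composition[i, 2]  # G column: complement of the 5' C
        assert g == 20

    def test_sites_without_full_flanks_dropped(self, toy_reference):
        sites = [
            ("chr1", i + 1)
            for i, b in enumerate(toy_reference["chr1"][:200])
            if b in "AT"
        ]
        res = window_context_test([("chr1", 1), *sites[:10]], sites[10:30],
                                  toy_reference, k=5, n_permutations=1000,
                                  rng=np.random.default_rng(4))
        assert res.n_dropped >= 1

    def test_empty_mutated_rejected(self, toy_reference):
        with pytest.raises(ValueError, match="empty"):
            window_context_test([], [("chr1", 10)], toy_reference, k=2)


def test_bh_adjustment_matches_step_up_oracle():
    """statsmodels' BH equals a direct implementation of the step-up rule."""
    rng = np.random.default_rng(8)
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(0, 1, size=int(rng.integers(2, 15)))
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(multipletests(p, method="fdr_bh")[1], adj)
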