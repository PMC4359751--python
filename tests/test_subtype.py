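import numpy as np
import pandas as pd
import pytest

from metaclone.io_formats import SUBTYPES, ExpressionMatrix, LesionMeta
from metaclone.subtype import (
    classify_matrix,
    classify_nearest_centroid,
    compare_private_burden,
    detect_switches,
    neighbour_concordance,
    select_variable_genes,
)


@pytest.fixture()
def toy_centroids():
    genes = [f"G{i}" for i in range(40)]
    c = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=list(SUBTYPES))
    for s, name in enumerate(SUBTYPES):
        c.iloc[10 * s : 10 * (s + 1), s] = 2.0
    return c


class TestNearestCentroid:
    def test_exact_centroid_recovers_itself(self, toy_centroids):
        profile = toy_centroids["pigmentation"].rename("L1")
        call = classify_nearest_centroid(profile, toy_centroids)
        assert call.assigned == "pigmentation" and call.margin > 0

    def test_negated_centroid_not_assigned_to_itself(self, toy_centroids):
        profile = (-1.0 * toy_centroids["proliferative"]).rename("L1")
        call = classify_nearest_centroid(profile, toy_centroids)
        assert call.assigned != "proliferative"
        assert call.correlations["proliferative"] < 0

    def test_gene_coverage_requirement(self, toy_centroids):
        profile = toy_centroids["pigmentation"].iloc[:10].rename("L1")
        with pytest.raises(ValueError, match="centroid genes"):
            classify_nearest_centroid(profile, toy_centroids)

    def test_affine_invariance_with_positive_scale(self, toy_centroids):
        rng = np.random.default_rng(1)
        profile = pd.Series(
            toy_centroids["high_immune"] + rng.normal(0, 0.5, 40), name="L1",
            index=toy_centroids.index,
        )
        base = classify_nearest_centroid(profile, toy_centroids)
        scaled = classify_nearest_centroid(3.0 * profile + 7.0, 3.0 * toy_centroids + 7.0)
        assert scaled.assigned == base.assigned
        for s in SUBTYPES:
            assert scaled.correlations[s] == pytest.approx(base.correlations[s])

    def test_noisy_recovery_rate(self, toy_centroids):
        """Centroid + Gaussian noise at half the signal amplitude is
        recovered for >= 95% of samples."""
        rng = np.random.default_rng(2)
        hits = 0
        for i in range(200):
            s = SUBTYPES[i % 4]
            profile = pd.Series(
                toy_centroids[s] + rng.normal(0, 1.0, 40), name=f"L{i}",
                index=toy_centroids.index,
            )
            hits += classify_nearest_centroid(profile, toy_centroids).assigned == s
        assert hits / 200 >= 0.95


class TestVariableGenes:
    def _matrix(self, values, genes=None):
        genes = genes or [f"G{i}" for i in range(len(values))]
        return ExpressionMatrix(
            pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=["S1", "S2", "S3"])
        )

    def test_top_three_of_four(self):
        m = self._matrix([[0, 4, 8], [0, 3, 6], [0, 2, 4], [0, 1, 2]])
        assert select_variable_genes(m, 0.75) == ["G0", "G1", "G2"]

    def test_constant_matrix_lexicographic(self):
        m = self._matrix([[1, 1, 1]] * 4, genes=["d", "b", "a", "c"])
        assert select_variable_genes(m, 0.5) == ["a", "b"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 3))
        m = self._matrix(values.tolist())
        got = select_variable_genes(m, 0.75)
        var = m.values.var(axis=1, ddof=1)
        expected = list(var.sort_values(ascending=False).index[:23])
        assert got == expected

    def test_nested_across_fractions(self):
        rng = np.random.default_rng(4)
        m = self._matrix(rng.normal(size=(20, 3)).tolist())
        previous: set = set()
        for frac in (0.25, 0.5, 0.75, 1.0):
            current = set(select_variable_genes(m, frac))
            assert previous <= current
            previous = current


def _cohort_matrix(rng, n_patients=6, within_sd=0.05, between_sd=3.0, n_genes=40):
    metas, cols = [], {}
    for p in range(n_patients):
        centre = rng.normal(0, between_sd, n_genes)
        pid = f"P{p}"
        for i in range(2):
            lid = f"{pid}_M{i + 1}"
            metas.append(
                LesionMeta(pid, lid, i + 1, subtype_label=SUBTYPES[p % 4])
            )
            cols[lid] = centre + rng.normal(0, within_sd, n_genes)
    genes = pd.Index([f"G{i}" for i in range(n_genes)], name="gene")
    return ExpressionMatrix(pd.DataFrame(cols, index=genes)), metas


class TestNeighbourConcordance:
    def test_tight_within_patient_profiles_all_concordant(self):
        rng = np.random.default_rng(5)
        matrix, metas = _cohort_matrix(rng)
        n, table, p = neighbour_concordance(matrix, metas)
        assert n == 6
        assert table.loc["phenotype_constant", "neighbours"] == 6
        assert 0 <= p <= 1

    def test_shuffled_lesions_rarely_concordant(self):
        rng = np.random.default_rng(6)
        matrix, metas = _cohort_matrix(rng, n_patients=8, within_sd=3.0, between_sd=0.0)
        n, _, _ = neighbour_concordance(matrix, metas)
        assert n <= 3  # near-chance pairing of 16 exchangeable leaves

    def test_association_detected_between_constancy_and_clustering(self):
        # half the patients have tight (constant-phenotype) pairs, half have
        # scrambled pairs labelled as switched
        rng = np.random.default_rng(7)
        metas, cols = [], {}
        for p in range(8):
            tight = p < 4
            pid = f"P{p}"
            centre = rng.normal(0, 3.0, 40)
            for i in range(2):
                lid = f"{pid}_M{i + 1}"
                label = SUBTYPES[0] if tight else SUBTYPES[i]
                metas.append(LesionMeta(pid, lid, i + 1, subtype_label=label))
                if not tight:  # switched patients: unrelated profiles
                    centre = rng.normal(0, 3.0, 40)
                cols[lid] = centre + rng.normal(0, 0.05, 40)
        matrix = ExpressionMatrix(
            pd.DataFrame(cols, index=pd.Index([f"G{i}" for i in range(40)], name="gene"))
        )
        _, table, p = neighbour_concordance(matrix, metas)
        assert table.loc["phenotype_constant", "neighbours"] == 4
        assert p < 0.2

    def test_adjacent_mode_weaker_than_pure_subtree(self):
        rng = np.random.default_rng(8)
        matrix, metas = _cohort_matrix(rng)
        n_pure, _, _ = neighbour_concordance(matrix, metas, mode="pure_subtree")
        n_adj, _, _ = neighbour_concordance(matrix, metas, mode="adjacent")
        assert n_adj >= n_pure


class TestDetectSwitches:
    def test_switch_into_proliferative(self):
        reports, summary = detect_switches({"P19": ["pigmentation", "proliferative"]})
        r = reports[0]
        assert r.switched and r.to_proliferative and not r.from_proliferative_violation
        assert summary["n_to_proliferative"] == 1

    def test_constant_proliferative_not_switched(self):
        (r,), _ = detect_switches({"P": ["proliferative", "proliferative"]})
        assert not r.switched and not r.to_proliferative

    def test_switch_out_of_proliferative_is_violation(self):
        (r,), _ = detect_switches({"P": ["proliferative", "pigmentation"]})
        assert r.switched and r.from_proliferative_violation

    def test_partition_of_switched_patients(self):
        import itertools

        seqs = {
            f"P{i}": list(s)
            for i, s in enumerate(itertools.product(SUBTYPES, repeat=2))
        }
        reports, summary = detect_switches(seqs)
        for r in reports:
            other = r.switched and not (r.to_proliferative or r.from_proliferative_violation)
            assert r.switched == (
                r.to_proliferative or r.from_proliferative_violation or other
            )
        assert summary["n_switched"] == sum(r.switched for r in reports) == 12

    def test_unknown_subtype_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            detect_switches({"P": ["pigmentation", "melanotic"]})


class TestPrivateBurden:
    def test_medians_and_ranges(self):
        res = compare_private_burden([27, 12, 52], [9, 0, 29, 15, 3])
        assert res["median_switch"] == 27 and res["range_switch"] == (12, 52)
        assert res["median_other"] == 9 and res["range_other"] == (0, 29)

    def test_identical_groups_p_one(self):
        res = compare_private_burden([5, 7, 9], [5, 7, 9])
        assert res["p"] == pytest.approx(1.0)

    def test_exact_method_for_small_untied_samples(self):
        res = compare_private_burden([27, 12, 52], [9, 1, 30])
        assert res["method"] == "exact"

    def test_power_at_planted_shift(self):
        """A clear burden shift is detected (p < 0.05) in >= 80% of draws."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(200)        :
            a = rng.poisson(27, size=6)
            b = rng.poisson(9, size=10)
            hits += compare_private_burden(a, b)["p"] < 0.05
        assert hits / 200 >= 0.8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_private_burden([], [1, 2])
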