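"""Replicated validation studies: recovery rates, calibration, oracles.

These drivers re-run the pipeline end to end on synthetic cohorts and
summarize how reliably each planted structure is recovered. They back the
reproducibility script and the heavier tests; every study takes an
explicit seed and returns plain numbers.
"""

from __future__ import annotations

import itertools

import numpy as np

from .clonality import estimate_multiplicity, expected_vaf
from .partition import partition_patient
from .progression import build_clone_tree, topology
from .simulate import SimConfig, patient1_config, simulate_cohort
from .spectrum import sample_coding_AT_sites, window_context_test
from .io_formats import GenomicVariant  # noqa: F401  (typing aid in docstrings)


def patient1_replicate_study(
    n_replicates: int = 100,
    seed: int = 0,
    n_permutations: int = 100_000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Simulate the heavily diverged 3-lesion structure repeatedly; check
    that the clone-tree topology is recovered and that the window test
    flags the planted +1/+2 context of the third lesion's private set.

    Returns fractions over replicates: ``topology_recovery`` (internal
    subsets and edge counts exact) and ``context_flag_rate`` (BH-adjusted
    p < alpha at both +1 and +2).
    """
    rng = np.random.default_rng(seed)
    topo_ok = flags = 0
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(patient1_config(), seed=rep_seed)
        pid = cohort.patients[0]
        lesions = cohort.lesions_of(pid)
        patterns, _ = partition_patient(
            cohort.variants, lesions, depth_lookup=cohort.site_depths
        )
        tree = build_clone_tree(patterns, lesions)
        planted = cohort.truth.tree_counts[pid]
        planted_topology = {s for s in planted if 1 < len(s) < len(lesions)}
        topo_ok += (
            topology(tree) == planted_topology
            and not tree.incompatible_patterns
            and all(tree.edge_count(s) == n for s, n in planted.items())
        )

        truth_cat = cohort.truth.category_of()
        m3 = lesions[-1]
        at_sites = [
            (v.chrom, v.pos)
            for v in cohort.variants
            if v.lesion_id == m3
            and v.ref in "AT"
            and truth_cat[v.key] == "private"
        ]
        random_sites = [
            (c, p)
            for c, p, _ in sample_coding_AT_sites(
                cohort.reference, cohort.coding, n=500, rng=rng
            )
        ]
        res = window_context_test(
            at_sites,
            random_sites,
            cohort.reference,
            k=5,
            n_permutations=n_permutations,
            rng=rng,
        )
        flags += res.p_at(1) < alpha and res.p_at(2) < alpha
    return {
        "topology_recovery": topo_ok / n_replicates,
        "context_flag_rate": flags / n_replicates,
        "n_replicates": n_replicates,
    }


def context_null_calibration(
    n_replicates: int = 500,
    seed: int = 0,
    n_mutated: int = 30,
    n_random: int = 500,
    k: int = 5,
    n_permutations: int = 100_000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the window composition test: mutated sites drawn
    from the same background as the random sites; returns the fraction of
    position tests with raw p below alpha."""
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(
        SimConfig(n_truncal=0, n_subset_shared=0, n_private=(0, 0, 0)), seed=seed
    )
    pool = sample_coding_AT_sites(
        cohort.reference, cohort.coding, n=20_000, rng=rng
    )
    low = 0
    total = 0
    for _ in range(n_replicates):
        idx = rng.choice(len(pool), size=n_mutated + n_random, replace=False)
        mutated = [(pool[i][0], pool[i][1]) for i in idx[:n_mutated]]
        background = [(pool[i][0], pool[i][1]) for i in idx[n_mutated:]]
        res = window_context_test(
            mutated,
            background,
            cohort.reference,
            k=k,
            n_permutations=n_permutations,
            rng=rng,
        )
        low += int((res.raw_p < alpha).sum())
        total += len(res.raw_p)
    return {
        "fraction_raw_p_below_alpha": low / total,
        "n_tests": total,
        "n_replicates": n_replicates,
    }


def multiplicity_recovery_grid(
    depth: int = 1000,
    n_draws: int = 400,
    max_cn: int = 4,
    purities: tuple[float, ...] = (0.6, 0.8, 1.0),
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of binomially sampled VAFs whose multiplicity estimate
    recovers the generating m, over all m <= cn <= max_cn and purities."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    key = ("chr1", 1, "C", "T")
    for cn in range(1, max_cn + 1):
        for m in range(1, cn + 1):
            for rho in purities:
                p = expected_vaf(m, cn, rho)
                vafs = rng.binomial(depth, p, size=n_draws) / depth
                for vaf in vafs:
                    call = estimate_multiplicity(key, "M", float(vaf), cn, rho)
                    hits += call.m_hat == m
                    total += 1
    return {"recovery": hits / total, "n_draws": total}


def _random_presence_cohort(rng, max_lesions=3, max_keys=50):
    n_lesions = int(rng.integers(2, max_lesions + 1))
    lesions = [f"M{i + 1}" for i in range(n_lesions)]
    n_keys = int(rng.integers(1, max_keys + 1))
    membership = {}
    for i in range(n_keys):
        present = frozenset(l for l in lesions if rng.random() < 0.5)
        if present:
            membership[("chr1", 100 + i, "C", "T")] = present
    return lesions, membership


def partition_oracle_study(n_cohorts: int = 200, seed: int = 0) -> dict[str, float]:
    """Partition vs an exhaustive set-algebra oracle on random cohorts.

    The oracle counts, for every nonempty lesion subset, the keys present
    in exactly that subset; agreement requires identical counts in every
    Venn region of every cohort.
    """
    from .io_formats import SiteDepthTable

    rng = np.random.default_rng(seed)
    agree = 0
    n_scored = 0
    for _ in range(n_cohorts):
        lesions, membership = _random_presence_cohort(rng)
        if not membership:
            continue
        n_scored += 1
        variants = []
        depths = SiteDepthTable()
        for key, present in membership.items():
            for lesion in lesions:
                if lesion in present:
                    variants.append(
                        GenomicVariant(
                            patient_id="P",
                            lesion_id=lesion,
                            chrom=key[0],
                            pos=key[1],
                            ref=key[2],
                            alt=key[3],
                            vaf=0.5,
                            depth=100,
                            alt_reads=50,
                        )
                    )
                else:
                    depths.add(lesion, key[0], key[1], 200, 0)
        _, summary = partition_patient(variants, lesions, depths)
        ok = True
        for r in range(1, len(lesions) + 1):
            for combo in itertools.combinations(lesions, r):
                expected = sum(
                    1 for present in membership.values() if present == frozenset(combo)
                )
                ok &= summary.count(*combo) == expected
        agree += ok
    return {"agreement": agree / n_scored, "n_cohorts": n_scored}


def progression_oracle_study(n_instances: int = 500, seed: int = 0) -> dict[str, float]:
    """Greedy clone-tree construction vs exhaustive laminar-family search
    on random 3-lesion instances: the number of mutations assigned to tree
    edges must equal the maximum achievable by any laminar subfamily."""
    from .partition import PresencePattern

    rng = np.random.default_rng(seed)
    lesions = ["M1", "M2", "M3"]
    proper = [
        frozenset(s)
        for r in (1, 2)
        for s in itertools.combinations(lesions, r)
    ]
    agree = 0
    for _ in range(n_instances):
        counts = {s: int(rng.integers(0, 8)) for s in proper}
        counts[frozenset(lesions)] = int(rng.integers(0, 8))
        patterns = []
        i = 0
        for subset, n in counts.items():
            for _ in range(n):
                bits = tuple(l in subset for l in lesions)
                k = sum(bits)
                patterns.append(
                    PresencePattern(
                        variant_key=("chr1", 100 + i, "C", "T"),
                        patient_id="P",
                        lesions=tuple(lesions),
                        bits=bits,
                        category=(
                            "truncal" if k == 3 else "private" if k == 1 else "shared_subset"
                        ),
                        unassessable_lesions=frozenset(),
                    )
                )
                i += 1
        tree = build_clone_tree(patterns, lesions)
        assigned = sum(tree.edge_count(n) for n in tree.nodes)
        observed = [s for s in proper if counts[s]]
        best = 0
        for r in range(len(observed) + 1):
            for family in itertools.combinations(observed, r):
                if all(
                    a <= b or b <= a or not (a & b)
                    for a, b in itertools.combinations(family, 2)
                ):
                    best = max(best, sum(counts[s] for s in family))
        best += counts[frozenset(lesions)]
        agree += assigned == best
    return {"agreement": agree / n_instances, "n_instances": n_instances}
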