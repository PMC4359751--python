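"""Expression phenotype classification and phenotype-switch analysis.

Lesions are assigned to one of four melanoma expression phenotypes
(pigmentation, proliferative, high_immune, normal_like) by nearest
centroid: Pearson correlation against a user-supplied centroid table,
argmax wins. Unsupervised checking uses hierarchical clustering on the
most variable genes; a patient whose lesions form a pure subtree of the
dendrogram is "concordant", and concordance is cross-tabulated against
phenotype constancy with a Fisher exact test. Temporal subtype sequences
are scanned for switches, in particular switches INTO the proliferative
phenotype (observed late-stage behaviour) and the never-observed switch
OUT of it.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, mannwhitneyu

from .io_formats import SUBTYPES, ExpressionMatrix, LesionMeta

logger = logging.getLogger("metaclone")


@dataclass(frozen=True)
class SubtypeCall:
    lesion_id: str
    correlations: dict[str, float]
    assigned: str
    margin: float


@dataclass(frozen=True)
class SwitchReport:
    patient_id: str
    sequence: tuple[str, ...]  # temporal order
    switched: bool
    to_proliferative: bool
    from_proliferative_violation: bool


def classify_nearest_centroid(
    profile: pd.Series, centroids: pd.DataFrame
) -> SubtypeCall:
    """Assign a lesion to the subtype with the highest Pearson correlation.

    Computed on the gene intersection, which must cover at least half the
    centroid genes. Exact ties go to the first subtype in the canonical
    order, with a warning.
    """
    shared = centroids.index.intersection(profile.index)
    if len(shared) < 0.5 * len(centroids.index):
        raise ValueError(
            f"only {len(shared)}/{len(centroids.index)} centroid genes in profile"
        )
    x = profile.loc[shared].to_numpy(dtype=float)
    correlations: dict[str, float] = {}
    for subtype in SUBTYPES:
        c = centroids.loc[shared, subtype].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(c) == 0:
            correlations[subtype] = 0.0
        else:
            correlations[subtype] = float(np.corrcoef(x, c)[0, 1])
    best = max(SUBTYPES, key=lambda s: correlations[s])
    ranked = sorted(correlations.values(), reverse=True)
    margin = ranked[0] - ranked[1]
    if margin == 0.0:
        logger.warning(
            "tied centroid correlations for %s; keeping %s by fixed subtype order",
            profile.name,
            best,
        )
    return SubtypeCall(
        lesion_id=str(profile.name),
        correlations=correlations,
        assigned=best,
        margin=margin,
    )


def classify_matrix(
    matrix: ExpressionMatrix, centroids: pd.DataFrame
) -> list[SubtypeCall]:
    return [
        classify_nearest_centroid(matrix.values[s], centroids) for s in matrix.samples
    ]


def select_variable_genes(matrix: ExpressionMatrix, fraction: float = 0.75) -> list[str]:
    """Top ``ceil(fraction * G)`` genes by variance across samples.

    Ties are broken by gene id (ascending) for determinism; a fully tied
    (e.g. constant) matrix therefore yields a lexicographic selection.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(matrix.genes) < 4:
        raise ValueError("need >= 4 genes")
    variances = matrix.values.var(axis=1, ddof=1)
    n = int(np.ceil(fraction * len(matrix.genes)))
    ranked = sorted(matrix.genes, key=lambda g: (-variances[g], g))
    if len(set(variances)) < len(variances):
        logger.info("variance ties present; gene-id tie-break applied")
    return ranked[:n]


def _pearson_distance(values: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns."""
    corr = np.corrcoef(values.to_numpy(dtype=float).T)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def _cluster_leafsets(link: np.ndarray, n: int) -> list[frozenset]:
    """Leaf-index sets of every internal cluster of a scipy linkage."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out: list[frozenset] = []
    for i, (a, b, _, _) in enumerate(link):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + i] = merged
        out.append(merged)
    return out


def neighbour_concordance(
    matrix: ExpressionMatrix,
    metas: Sequence[LesionMeta],
    calls: Sequence[SubtypeCall] | None = None,
    fraction: float = 0.75,
    distance: str = "pearson",
    linkage_method: str = "average",
    mode: str = "pure_subtree",
):
    """Do each patient's lesions cluster together, and does that track
    phenotype constancy?

    Hierarchical clustering (default 1 - Pearson, average linkage) on the
    variable genes; a patient is a "closest neighbour" patient when its
    lesions form a pure subtree (``mode='pure_subtree'``) or occupy
    adjacent leaves (``mode='adjacent'``). Returns (number of concordant
    patients, 2x2 DataFrame phenotype-constant x neighbours, two-sided
    Fisher exact p).
    """
    if mode not in ("pure_subtree", "adjacent"):
        raise ValueError(f"unknown mode {mode!r}")
    by_patient: dict[str, list[str]] = {}
    for m in sorted(metas, key=lambda m: m.order_index):
        if m.lesion_id in matrix.samples:
            by_patient.setdefault(m.patient_id, []).append(m.lesion_id)
    multi = {p: ls for p, ls in by_patient.items() if len(ls) >= 2}
    if len(multi) < 2:
        raise ValueError("need >= 2 patients with >= 2 profiled lesions")

    genes = select_variable_genes(matrix, fraction)
    values = matrix.values.loc[genes]
    if distance == "pearson":
        condensed = _pearson_distance(values)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(values.to_numpy(dtype=float).T)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    link = linkage(condensed, method=linkage_method)
    samples = matrix.samples
    index_of = {s: i for i, s in enumerate(samples)}
    leafsets = _cluster_leafsets(link, len(samples))
    leaf_order = list(leaves_list(link))
    position = {leaf: pos for pos, leaf in enumerate(leaf_order)}

    label_of = {c.lesion_id: c.assigned for c in calls or []}
    if not label_of:
        label_of = {m.lesion_id: m.subtype_label for m in metas if m.subtype_label}

    rows = []
    n_concordant = 0
    for patient, lesions in sorted(multi.items()):
        idx = frozenset(index_of[l] for l in lesions)
        if mode == "pure_subtree":
            concordant = idx in leafsets
        else:
            pos = sorted(position[i] for i in idx)
            concordant = pos[-1] - pos[0] == len(pos) - 1
        labels = {label_of.get(l) for l in lesions}
        if None in labels:
            raise ValueError(f"missing subtype label for a lesion of patient {patient}")
        constant = len(labels) == 1
        n_concordant += concordant
        rows.append({"patient_id": patient, "constant": constant, "neighbours": concordant})
    df = pd.DataFrame(rows)
    table = pd.DataFrame(
        [
            [
                int(((df.constant) & (df.neighbours)).sum()),
                int(((df.constant) & (~df.neighbours)).sum()),
            ],
            [
                int(((~df.constant) & (df.neighbours)).sum()),
                int(((~df.constant) & (~df.neighbours)).sum()),
            ],
        ],
        index=["phenotype_constant", "phenotype_change"],
        columns=["neighbours", "not_neighbours"],
    )
    _, p = fisher_exact(table.to_numpy(), alternative="two-sided")
    return n_concordant, table, float(p)


def detect_switches(
    sequences: Mapping[str, Sequence[str]],
) -> tuple[list[SwitchReport], dict[str, int]]:
    """Scan temporally ordered subtype sequences for phenotype switches.

    ``to_proliferative``: a proliferative lesion follows a
    non-proliferative one. ``from_proliferative_violation``: a
    proliferative lesion precedes a lesion of a different class — never
    observed in the study, hence flagged as a rule violation.
    """
    reports: list[SwitchReport] = []
    for patient, seq in sequences.items():
        seq = tuple(seq)
        if len(seq) < 2:
            raise ValueError(f"patient {patient}: need >= 2 temporally ordered lesions")
        unknown = set(seq) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"patient {patient}: unknown subtypes {sorted(unknown)}")
        switched = len(set(seq)) > 1
        to_prolif = any(
            a != "proliferative" and b == "proliferative" for a, b in zip(seq, seq[1:])
        )
        from_prolif = any(
            a == "proliferative" and b != "proliferative" for a, b in zip(seq, seq[1:])
        )
        reports.append(
            SwitchReport(
                patient_id=patient,
                sequence=seq,
                switched=switched,
                to_proliferative=to_prolif,
                from_proliferative_violation=from_prolif,
            )
        )
    summary = {
        "n_patients": len(reports),
        "n_switched": sum(r.switched for r in reports),
        "n_to_proliferative": sum(r.to_proliferative for r in reports),
        "n_from_proliferative_violation": sum(
            r.from_proliferative_violation for r in reports
        ),
    }
    return reports, summary


def compare_private_burden(
    switch_group: Sequence[float], other_group: Sequence[float]
) -> dict:
    """Median/range of private event burden per group + Mann-Whitney p.

    Exact two-sided p for small samples without ties; with ties or large
    samples scipy falls back to the asymptotic normal approximation
    (no continuity correction; the choice is reported in the result).
    """
    a = np.asarray(switch_group, dtype=float)
    b = np.asarray(other_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    stat, p = mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return {
        "median_switch": float(np.median(a)),
        "range_switch": (float(a.min()), float(a.max())),
        "median_other": float(np.median(b)),
        "range_other": (float(b.min()), float(b.max())),
        "U": float(stat),
        "p": float(p),
        "method": method,
    }
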