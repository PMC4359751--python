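"""Shared/private partitioning of somatic variants across a patient's lesions.

Each variant key observed anywhere in a patient is scored per lesion as
present (called in that lesion), absent (adequately covered with near-zero
alt fraction), or unassessable (insufficient coverage to rule it out).
Fully assessable patterns are categorised truncal (all lesions), shared
subset (>= 2 but not all) or private (exactly one); any unassessable
lesion makes the whole pattern unassessable, and such patterns are
excluded from the Venn-region counts but reported.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io_formats import GenomicVariant, SiteDepthTable

DEFAULT_MIN_DEPTH = 20
DEFAULT_MAX_ABSENT_VAF = 0.02

DRIVER_GENES = frozenset({"BRAF", "NRAS"})

#: lesion-level presence states
PRESENT, ABSENT, UNASSESSABLE = "present", "absent", "unassessable"


@dataclass(frozen=True)
class PresencePattern:
    variant_key: tuple[str, int, str, str]
    patient_id: str
    lesions: tuple[str, ...]  # temporal order
    bits: tuple[bool, ...]  # presence per lesion
    category: str  # truncal | shared_subset | private | unassessable
    unassessable_lesions: frozenset[str]
    gene: str = ""

    @property
    def present_lesions(self) -> frozenset[str]:
        return frozenset(l for l, b in zip(self.lesions, self.bits) if b)


@dataclass(frozen=True)
class PartitionSummary:
    patient_id: str
    lesions: tuple[str, ...]
    region_counts: Mapping[frozenset, int]  # nonempty lesion subsets -> count
    n_unassessable: int

    def count(self, *lesions: str) -> int:
        return self.region_counts.get(frozenset(lesions), 0)

    @property
    def n_assessable(self) -> int:
        return sum(self.region_counts.values())


def presence_call(
    called: bool,
    depth: int | None,
    alt_reads: int | None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_absent_vaf: float = DEFAULT_MAX_ABSENT_VAF,
) -> str:
    """Presence state of one variant key in one lesion.

    ``called`` is whether the lesion's own call set contains the key;
    depth/alt_reads describe the lesion's coverage at the site (None when
    unknown). Absence requires depth >= min_depth and an observed alt
    fraction below max_absent_vaf.
    """
    if min_depth <= 0:
        raise ValueError("min_depth must be > 0")
    if not 0.0 <= max_absent_vaf < 0.5:
        raise ValueError("max_absent_vaf must be in [0, 0.5)")
    if called:
        return PRESENT
    if depth is None or alt_reads is None:
        return UNASSESSABLE
    if depth < 0 or alt_reads < 0:
        raise ValueError("negative depth or alt_reads")
    if depth >= min_depth and alt_reads / depth < max_absent_vaf:
        return ABSENT
    return UNASSESSABLE


def partition_patient(
    variants: Sequence[GenomicVariant],
    lesions: Sequence[str],
    depth_lookup: SiteDepthTable | Callable[[str, str, int], tuple[int, int] | None] | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_absent_vaf: float = DEFAULT_MAX_ABSENT_VAF,
) -> tuple[list[PresencePattern], PartitionSummary]:
    """Partition one patient's variants into presence patterns + Venn counts.

    ``lesions`` must be the patient's lesion ids in temporal order (>= 2).
    ``depth_lookup`` supplies (depth, alt_reads) at a site for lesions where
    the variant was not called; without it every non-called lesion is
    unassessable.
    """
    if len(lesions) < 2:
        raise ValueError("partitioning requires >= 2 lesions (study inclusion rule)")
    lesion_set = set(lesions)
    patients = {v.patient_id for v in variants}
    if len(patients) > 1:
        raise ValueError(f"variants span multiple patients: {sorted(patients)}")
    for v in variants:
        if v.lesion_id not in lesion_set:
            raise ValueError(f"variant lesion {v.lesion_id!r} not in patient lesions {lesions}")
    patient_id = patients.pop() if patients else ""

    if isinstance(depth_lookup, SiteDepthTable):
        lookup = depth_lookup.get
    else:
        lookup = depth_lookup

    called: dict[tuple, dict[str, GenomicVariant]] = {}
    order: list[tuple] = []
    for v in variants:
        if v.key not in called:
            called[v.key] = {}
            order.append(v.key)
        called[v.key][v.lesion_id] = v

    patterns: list[PresencePattern] = []
    for key in order:
        per_lesion = called[key]
        states = {}
        for lesion in lesions:
            if lesion in per_lesion:
                states[lesion] = PRESENT
            else:
                chrom, pos = key[0], key[1]
                da = lookup(lesion, chrom, pos) if lookup else None
                depth, alt = da if da is not None else (None, None)
                states[lesion] = presence_call(False, depth, alt, min_depth, max_absent_vaf)
        bits = tuple(states[l] == PRESENT for l in lesions)
        unassessable = frozenset(l for l in lesions if states[l] == UNASSESSABLE)
        n_present = sum(bits)
        if unassessable:
            category = "unassessable"
        elif n_present == len(lesions):
            category = "truncal"
        elif n_present == 1:
            category = "private"
        else:
            category = "shared_subset"
        gene = next(iter(per_lesion.values())).gene
        patterns.append(
            PresencePattern(
                variant_key=key,
                patient_id=patient_id,
                lesions=tuple(lesions),
                bits=bits,
                category=category,
                unassessable_lesions=unassessable,
                gene=gene,
            )
        )

    region_counts: dict[frozenset, int] = {}
    n_unassessable = 0
    for p in patterns:
        if p.category == "unassessable":
            n_unassessable += 1
            continue
        region_counts[p.present_lesions] = region_counts.get(p.present_lesions, 0) + 1
    summary = PartitionSummary(
        patient_id=patient_id,
        lesions=tuple(lesions),
        region_counts=region_counts,
        n_unassessable=n_unassessable,
    )
    return patterns, summary


@dataclass(frozen=True)
class DriverViolation:
    variant_key: tuple[str, int, str, str]
    gene: str
    present_lesion: str
    absent_lesion: str


def check_driver_preservation(
    patterns: Sequence[PresencePattern],
    driver_genes: frozenset[str] = DRIVER_GENES,
) -> list[DriverViolation]:
    """Report driver variants present in an earlier lesion yet absent later.

    Absence must be affirmative (adequately covered); unassessable later
    lesions do not count as violations. An empty report means every driver
    present early was preserved downstream.
    """
    violations: list[DriverViolation] = []
    for p in patterns:
        if p.gene not in driver_genes:
            continue
        for i, j in combinations(range(len(p.lesions)), 2):
            earlier, later = p.lesions[i], p.lesions[j]
            if p.bits[i] and not p.bits[j] and later not in p.unassessable_lesions:
                violations.append(
                    DriverViolation(
                        variant_key=p.variant_key,
                        gene=p.gene,
                        present_lesion=earlier,
                        absent_lesion=later,
                    )
                )
    return violations


def patterns_to_frame(patterns: Sequence[PresencePattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        row = {
            "patient_id": p.patient_id,
            "chrom": p.variant_key[0],
            "pos": p.variant_key[1],
            "ref": p.variant_key[2],
            "alt": p.variant_key[3],
            "gene": p.gene,
            "category": p.category,
            "unassessable_lesions": ",".join(sorted(p.unassessable_lesions)),
        }
        for lesion, bit in zip(p.lesions, p.bits):
            row[f"in_{lesion}"] = int(bit)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_to_frame(summary: PartitionSummary) -> pd.DataFrame:
    """Venn-region counts as a tidy table (machine-readable Venn diagram)."""
    rows = []
    for subset in sorted(summary.region_counts, key=lambda s: (len(s), sorted(s))):
        rows.append(
            {
                "patient_id": summary.patient_id,
                "lesions": ",".join(l for l in summary.lesions if l in subset),
                "n_lesions": len(subset),
                "count": summary.region_counts[subset],
            }
        )
    rows.append(
        {
            "patient_id": summary.patient_id,
            "lesions": "unassessable",
            "n_lesions": 0,
            "count": summary.n_unassessable,
        }
    )
    return pd.DataFrame(rows, columns=["patient_id", "lesions", "n_lesions", "count"])
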