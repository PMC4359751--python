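"""Mutant-allele multiplicity from VAF, copy number and purity.

For a clonal mutation carried on ``m`` of ``total_cn`` tumour copies in a
sample of purity rho (germline copy number 2 on autosomes), the expected
variant allele frequency is

    E[VAF] = m * rho / (total_cn * rho + 2 * (1 - rho))

The multiplicity estimate is the integer m in 1..total_cn whose expected
VAF is nearest the observed one; a mutation whose VAF sits within a fixed
tolerance of that expectation is flagged clonal, otherwise subclonal. A
VAF exceeding even the all-copies expectation (plus tolerance) raises a
"super-clonal" flag, which usually means the purity or copy number at the
locus is misspecified.

Summing multiplicities of inactivating hits in a tumour-suppressor gene
against the locus copy number detects multi-hit inactivation: e.g. two
hits with VAFs 0.30 and 0.55 at copy number 3 in a pure sample imply
multiplicities 1 and 2, i.e. all three alleles hit.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    INACTIVATING_EFFECTS,
    GenomicVariant,
    SegmentIndex,
)

DEFAULT_CLONAL_TOL = 0.10

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class MultiplicityCall:
    variant_key: tuple[str, int, str, str]
    lesion_id: str
    vaf: float
    total_cn: int
    purity: float
    expected_vaf_by_m: dict[int, float]
    m_hat: int
    clonal_flag: bool
    superclonal_flag: bool = False


@dataclass(frozen=True)
class GeneHitSummary:
    gene: str
    lesion_id: str
    hits: tuple[MultiplicityCall, ...]
    total_cn: int
    inferred_inactivated_alleles: int
    biallelic_flag: bool
    mixed_cn_flag: bool = False


def expected_vaf(m: int, total_cn: int, purity: float) -> float:
    """Expected VAF of a clonal mutation on m of total_cn tumour copies."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity {purity} outside (0, 1]")
    if total_cn == 0:
        raise ValueError("total_cn = 0 cannot carry a mutation")
    if not 1 <= m <= total_cn:
        raise ValueError(f"m = {m} outside 1..total_cn = {total_cn}")
    return m * purity / (total_cn * purity + 2.0 * (1.0 - purity))


def estimate_multiplicity(
    variant_key: tuple[str, int, str, str],
    lesion_id: str,
    vaf: float,
    total_cn: int,
    purity: float = 1.0,
    tol: float = DEFAULT_CLONAL_TOL,
) -> MultiplicityCall:
    """Nearest-expectation multiplicity call; ties go to the smaller m."""
    if total_cn < 1:
        raise ValueError(f"total_cn must be >= 1, got {total_cn}")
    expected = {m: expected_vaf(m, total_cn, purity) for m in range(1, total_cn + 1)}
    # min() scans ascending m, so exact ties resolve to the smaller m
    m_hat = min(expected, key=lambda m: abs(vaf - expected[m]))
    residual = abs(vaf - expected[m_hat])
    superclonal = vaf > expected[total_cn] + tol
    return MultiplicityCall(
        variant_key=variant_key,
        lesion_id=lesion_id,
        vaf=vaf,
        total_cn=total_cn,
        purity=purity,
        expected_vaf_by_m=expected,
        m_hat=m_hat,
        clonal_flag=residual <= tol,
        superclonal_flag=superclonal,
    )


def call_variant_multiplicity(
    variant: GenomicVariant,
    seg_index: SegmentIndex,
    purity: float = 1.0,
    tol: float = DEFAULT_CLONAL_TOL,
) -> MultiplicityCall | None:
    """Multiplicity call for one observed variant, or None when the site is
    uncovered by segments, on a sex chromosome, or at copy number 0."""
    if variant.chrom in SEX_CHROMS:
        return None
    cn = seg_index.cn_at(variant.lesion_id, variant.chrom, variant.pos)
    if cn is None or cn == 0:
        return None
    return estimate_multiplicity(variant.key, variant.lesion_id, variant.vaf, cn, purity, tol)


def summarize_gene_hits(
    hits: Sequence[GenomicVariant],
    seg_index: SegmentIndex,
    purity: float = 1.0,
    inactivating_effects: frozenset[str] = INACTIVATING_EFFECTS,
    tol: float = DEFAULT_CLONAL_TOL,
) -> GeneHitSummary:
    """Sum inactivating-hit multiplicities against the locus copy number.

    All hits must lie in one gene and one lesion. When hits span segments
    of different copy number, each hit uses its own segment's CN and the
    summary is flagged mixed-CN with the locus CN taken as the maximum.
    """
    if not hits:
        raise ValueError("no hits supplied")
    genes = {v.gene for v in hits}
    lesions = {v.lesion_id for v in hits}
    if len(genes) != 1 or len(lesions) != 1:
        raise ValueError(f"hits span genes {genes} / lesions {lesions}; expected one of each")
    calls = []
    cns = []
    for v in hits:
        call = call_variant_multiplicity(v, seg_index, purity=purity, tol=tol)
        if call is None:
            raise ValueError(f"no copy-number segment covers {v.chrom}:{v.pos} in {v.lesion_id}")
        calls.append(call)
        cns.append(call.total_cn)
    locus_cn = max(cns)
    inactivating = [
        c for c, v in zip(calls, hits) if v.effect in inactivating_effects
    ]
    n_alleles = sum(c.m_hat for c in inactivating)
    return GeneHitSummary(
        gene=genes.pop(),
        lesion_id=lesions.pop(),
        hits=tuple(calls),
        total_cn=locus_cn,
        inferred_inactivated_alleles=n_alleles,
        biallelic_flag=n_alleles >= locus_cn,
        mixed_cn_flag=len(set(cns)) > 1,
    )


def vaf_cn_table(
    patterns,
    variants: Iterable[GenomicVariant],
    seg_index: SegmentIndex,
    purity_of_lesion=None,
    tol: float = DEFAULT_CLONAL_TOL,
) -> pd.DataFrame:
    """Per-lesion (variant, log2 CN, VAF, category) records for the
    copy-number-versus-VAF scatter; one row per variant x lesion observed.

    ``patterns`` is the output of :func:`metaclone.partition.partition_patient`
    (used only for the category column); variants on segments without
    coverage get a missing CN and are flagged.
    """
    import numpy as np

    category_of = {p.variant_key: p.category for p in patterns}
    rows = []
    for v in variants:
        cn = seg_index.cn_at(v.lesion_id, v.chrom, v.pos)
        purity = purity_of_lesion(v.lesion_id) if purity_of_lesion else 1.0
        if cn is None:
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "lesion_id": v.lesion_id,
                    "gene": v.gene,
                    "total_cn": np.nan,
                    "log2_cn": np.nan,
                    "vaf": v.vaf,
                    "category": category_of.get(v.key, "unassessable"),
                    "m_hat": np.nan,
                    "clonal": pd.NA,
                    "cn_missing": True,
                }
            )
            continue
        call = (
            estimate_multiplicity(v.key, v.lesion_id, v.vaf, cn, purity, tol)
            if cn >= 1 and v.chrom not in SEX_CHROMS
            else None
        )
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "lesion_id": v.lesion_id,
                "gene": v.gene,
                "total_cn": cn,
                "log2_cn": np.log2(cn) if cn > 0 else np.nan,
                "vaf": v.vaf,
                "category": category_of.get(v.key, "unassessable"),
                "m_hat": call.m_hat if call else np.nan,
                "clonal": call.clonal_flag if call else pd.NA,
                "cn_missing": False,
            }
        )
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "lesion_id",
        "gene",
        "total_cn",
        "log2_cn",
        "vaf",
        "category",
        "m_hat",
        "clonal",
        "cn_missing",
    ]
    return pd.DataFrame(rows, columns=cols)
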