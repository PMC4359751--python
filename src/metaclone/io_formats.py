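"""Domain types and file formats for the multi-lesion analysis pipeline.

All downstream modules consume only the types defined here. Coordinate
convention: 1-based inclusive on disk (VCF/SEG), 0-based half-open
internally for intervals; point positions (variant ``pos``, breakend
positions) stay 1-based throughout because that is how they are compared
and reported. Conversions are confined to this module.

TSV dialects (all tab-separated, with header):

* variants:    patient_id lesion_id chrom pos ref alt gene effect vaf depth alt_reads
* segments:    lesion_id chrom start end total_cn [log2_ratio]   (SEG-style, 1-based inclusive)
* breakends:   BEDPE — chrom1 start1 end1 chrom2 start2 end2 lesion_id supporting_reads
* metadata:    patient_id lesion_id order_index site purity ploidy [subtype_label]
* expression:  first column ``gene``, one column per lesion (log2 values)
* centroids:   first column ``gene``, one column per subtype
* site depths: lesion_id chrom pos depth alt_reads
"""

from __future__ import annotations

import bisect
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("metaclone")

EFFECTS = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "splice_site",
        "frameshift",
        "inframe_indel",
        "intronic",
        "other",
    }
)

#: loss-of-function effect classes used for tumour-suppressor hit counting
INACTIVATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice_site"})

SUBTYPES = ("pigmentation", "proliferative", "high_immune", "normal_like")

_NUCS = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line when known."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicVariant:
    """One somatic SNV/indel observed in one lesion.

    ``pos`` is the 1-based position of the first reference base. ``vaf``
    must agree with ``alt_reads / depth`` to within 0.01 when depth > 0.
    """

    patient_id: str
    lesion_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_reads: int
    gene: str = ""
    effect: str = "other"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("depth and alt_reads must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} > depth {self.depth} at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.01:
            raise ValueError(
                f"vaf {self.vaf} disagrees with alt_reads/depth "
                f"{self.alt_reads}/{self.depth} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: exact (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and {self.ref, self.alt} <= _NUCS


@dataclass(frozen=True)
class CopyNumberSegment:
    """Integer total copy number over ``[start, end)`` (0-based half-open)."""

    lesion_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    log2_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0:
            raise ValueError(f"negative total_cn {self.total_cn}")


@dataclass(frozen=True)
class LesionMeta:
    patient_id: str
    lesion_id: str
    order_index: int
    site: str = ""
    purity: float = 1.0
    ploidy: float = 2.0
    subtype_label: str | None = None

    def __post_init__(self) -> None:
        if self.order_index < 1:
            raise ValueError("order_index must be >= 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.subtype_label is not None and self.subtype_label not in SUBTYPES:
            raise ValueError(f"unknown subtype_label {self.subtype_label!r}")


@dataclass(frozen=True)
class BreakendCall:
    """One interchromosomal junction in one lesion (positions 1-based)."""

    lesion_id: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.chromA == self.chromB:
            raise ValueError("only interchromosomal breakends are handled")
        if self.posA < 1 or self.posB < 1:
            raise ValueError("breakend positions are 1-based (>= 1)")


class ExpressionMatrix:
    """Genes x samples log2 expression values backed by a DataFrame."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


# ---------------------------------------------------------------------------
# chromosome-name handling
# ---------------------------------------------------------------------------


def check_chrom_naming(chroms: Iterable[str]) -> None:
    """Reject mixed ``chr``-prefixed and bare chromosome names in one file."""
    names = set(chroms)
    with_prefix = {c for c in names if c.startswith("chr")}
    if with_prefix and with_prefix != names:
        raise FormatError(
            f"mixed chromosome naming: {sorted(with_prefix)[:3]} vs "
            f"{sorted(names - with_prefix)[:3]}"
        )


def normalize_chrom(chrom: str, use_prefix: bool) -> str:
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{bare}" if use_prefix else bare


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "vaf",
    "depth",
    "alt_reads",
]


def read_variants(
    path,
    dialect: str = "tsv",
    patient_id: str | None = None,
    lesion_of_sample: Mapping[str, str] | None = None,
) -> list[GenomicVariant]:
    """Read somatic variants from a TSV (documented dialect) or a VCF.

    For the VCF dialect the per-sample lesion id is the VCF sample name
    (overridable via ``lesion_of_sample``) and ``patient_id`` is required.
    VAF is taken from the AD ratio when present, else the AF tag with DP;
    if both exist and disagree by more than 0.01 the record is rejected.
    Multi-allelic records are split into one variant per alt.
    """
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path, patient_id, lesion_of_sample)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path) -> list[GenomicVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing}")
    check_chrom_naming(df["chrom"])
    out: list[GenomicVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            out.append(
                GenomicVariant(
                    patient_id=row.patient_id,
                    lesion_id=row.lesion_id,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    effect=row.effect,
                    vaf=float(row.vaf),
                    depth=int(row.depth),
                    alt_reads=int(row.alt_reads),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return out


def _read_variants_vcf(
    path, patient_id: str | None, lesion_of_sample: Mapping[str, str] | None
) -> list[GenomicVariant]:
    from cyvcf2 import VCF

    if patient_id is None:
        raise ValueError("patient_id is required for the VCF dialect")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    out: list[GenomicVariant] = []
    chroms: set[str] = set()
    for rec in vcf:
        chroms.add(rec.CHROM)
        ad = rec.format("AD")  # (n_samples, 1 + n_alt) or None
        af = rec.format("AF")
        dp = rec.format("DP")
        gene = dict(rec.INFO).get("GENE", "") or ""
        effect = dict(rec.INFO).get("EFFECT", "other") or "other"
        for ai, alt in enumerate(rec.ALT):
            for si, sample in enumerate(samples):
                lesion = lesion_of_sample[sample] if lesion_of_sample else sample
                if ad is not None:
                    counts = np.asarray(ad[si], dtype=float)
                    if np.any(counts < 0):  # missing AD encoded as -1
                        raise FormatError(
                            f"{path}: missing AD for sample {sample} at "
                            f"{rec.CHROM}:{rec.POS}"
                        )
                    depth = int(counts.sum())
                    alt_reads = int(counts[1 + ai])
                    vaf = alt_reads / depth if depth else 0.0
                    if af is not None:
                        af_val = float(np.asarray(af[si]).ravel()[ai])
                        if depth and abs(af_val - vaf) > 0.01:
                            raise FormatError(
                                f"{path}: AD-derived VAF {vaf:.3f} conflicts with "
                                f"AF {af_val:.3f} at {rec.CHROM}:{rec.POS} ({sample})"
                            )
                elif af is not None and dp is not None:
                    vaf = float(np.asarray(af[si]).ravel()[ai])
                    depth = int(np.asarray(dp[si]).ravel()[0])
                    alt_reads = int(round(vaf * depth))
                else:
                    raise FormatError(
                        f"{path}: neither AD nor AF+DP present at {rec.CHROM}:{rec.POS}"
                    )
                out.append(
                    GenomicVariant(
                        patient_id=patient_id,
                        lesion_id=lesion,
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        gene=str(gene),
                        effect=str(effect) if effect in EFFECTS else "other",
                        vaf=vaf,
                        depth=depth,
                        alt_reads=alt_reads,
                    )
                )
    check_chrom_naming(chroms)
    return out


def write_variants(variants: Sequence[GenomicVariant], path) -> None:
    df = pd.DataFrame([{c: getattr(v, c) for c in _VARIANT_COLUMNS} for v in variants])
    if df.empty:
        df = pd.DataFrame(columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------


def read_segments(path) -> list[CopyNumberSegment]:
    """Read SEG-style segments (1-based inclusive on disk).

    Per-lesion, per-chromosome segments must be non-overlapping; abutting
    segments are kept distinct, never merged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        return []
    rename = {"sample": "lesion_id", "ID": "lesion_id"}
    df = df.rename(columns=rename)
    required = ["lesion_id", "chrom", "start", "end", "total_cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing segment columns {missing}")
    check_chrom_naming(df["chrom"])
    segs: list[CopyNumberSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            log2 = getattr(row, "log2_ratio", "")
            segs.append(
                CopyNumberSegment(
                    lesion_id=row.lesion_id,
                    chrom=row.chrom,
                    start=int(row.start) - 1,
                    end=int(row.end),
                    total_cn=int(row.total_cn),
                    log2_ratio=float(log2) if log2 != "" else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    _check_segment_overlap(segs, str(path))
    return sorted(segs, key=lambda s: (s.lesion_id, s.chrom, s.start))


def _check_segment_overlap(segs: Sequence[CopyNumberSegment], source: str) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segs:
        by_key.setdefault((s.lesion_id, s.chrom), []).append(s)
    for (lesion, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"{source}: overlapping segments for {lesion}/{chrom}: "
                    f"{a.start + 1}-{a.end} and {b.start + 1}-{b.end}"
                )


def write_segments(segments: Sequence[CopyNumberSegment], path) -> None:
    rows = [
        {
            "lesion_id": s.lesion_id,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "total_cn": s.total_cn,
            "log2_ratio": "" if s.log2_ratio is None else f"{s.log2_ratio:.9g}",
        }
        for s in segments
    ]
    cols = ["lesion_id", "chrom", "start", "end", "total_cn", "log2_ratio"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


class SegmentIndex:
    """Bisect-backed point lookup of total copy number.

    Built once per segment list; queries take a 1-based position and
    return the covering segment's total_cn or None when uncovered.
    """

    def __init__(self, segments: Iterable[CopyNumberSegment]):
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._segs: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for s in segments:
            by_key.setdefault((s.lesion_id, s.chrom), []).append(s)
        for key, group in by_key.items():
            group = sorted(group, key=lambda s: s.start)
            self._segs[key] = group
            self._starts[key] = [s.start for s in group]

    def segment_at(self, lesion_id: str, chrom: str, pos: int) -> CopyNumberSegment | None:
        key = (lesion_id, chrom)
        if key not in self._segs:
            return None
        pos0 = pos - 1
        i = bisect.bisect_right(self._starts[key], pos0) - 1
        if i < 0:
            return None
        seg = self._segs[key][i]
        return seg if pos0 < seg.end else None

    def cn_at(self, lesion_id: str, chrom: str, pos: int) -> int | None:
        seg = self.segment_at(lesion_id, chrom, pos)
        return None if seg is None else seg.total_cn

    def segments_for(self, lesion_id: str) -> list[CopyNumberSegment]:
        out: list[CopyNumberSegment] = []
        for (lesion, _), group in sorted(self._segs.items()):
            if lesion == lesion_id:
                out.extend(group)
        return out


def lookup_cn(
    segments: Sequence[CopyNumberSegment], lesion_id: str, chrom: str, pos: int
) -> int | None:
    """Total copy number covering 1-based ``pos``; None when uncovered."""
    return SegmentIndex(segments).cn_at(lesion_id, chrom, pos)


# ---------------------------------------------------------------------------
# breakends (BEDPE)
# ---------------------------------------------------------------------------

_BEDPE_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "lesion_id",
    "supporting_reads",
]


def read_breakends(path) -> list[BreakendCall]:
    """Read interchromosomal breakends from BEDPE (0-based half-open on disk)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= 1:
        return []
    missing = [c for c in _BEDPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing BEDPE columns {missing}")
    check_chrom_naming(list(df["chrom1"]) + list(df["chrom2"]))
    out: list[BreakendCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                BreakendCall(
                    lesion_id=row.lesion_id,
                    chromA=row.chrom1,
                    posA=int(row.start1) + 1,
                    chromB=row.chrom2,
                    posB=int(row.start2) + 1,
                    supporting_reads=int(row.supporting_reads),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_breakends(breakends: Sequence[BreakendCall], path) -> None:
    rows = [
        {
            "chrom1": b.chromA,
            "start1": b.posA - 1,
            "end1": b.posA,
            "chrom2": b.chromB,
            "start2": b.posB - 1,
            "end2": b.posB,
            "lesion_id": b.lesion_id,
            "supporting_reads": b.supporting_reads,
        }
        for b in breakends
    ]
    pd.DataFrame(rows, columns=_BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# lesion metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["patient_id", "lesion_id", "order_index", "site", "purity", "ploidy"]


def read_metadata(path) -> list[LesionMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    metas: list[LesionMeta] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sub = getattr(row, "subtype_label", "")
            metas.append(
                LesionMeta(
                    patient_id=row.patient_id,
                    lesion_id=row.lesion_id,
                    order_index=int(row.order_index),
                    site=row.site,
                    purity=float(row.purity),
                    ploidy=float(row.ploidy),
                    subtype_label=sub if sub else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    _check_unique_order(metas)
    return metas


def _check_unique_order(metas: Sequence[LesionMeta]) -> None:
    seen: dict[tuple[str, int], str] = {}
    for m in metas:
        key = (m.patient_id, m.order_index)
        if key in seen:
            raise FormatError(
                f"duplicate order_index {m.order_index} in patient {m.patient_id} "
                f"({seen[key]} and {m.lesion_id})"
            )
        seen[key] = m.lesion_id


def write_metadata(metas: Sequence[LesionMeta], path) -> None:
    rows = [
        {
            "patient_id": m.patient_id,
            "lesion_id": m.lesion_id,
            "order_index": m.order_index,
            "site": m.site,
            "purity": f"{m.purity:.9g}",
            "ploidy": f"{m.ploidy:.9g}",
            "subtype_label": m.subtype_label or "",
        }
        for m in metas
    ]
    cols = _META_COLUMNS + ["subtype_label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def lesions_in_order(metas: Sequence[LesionMeta], patient_id: str) -> list[str]:
    """Lesion ids of one patient sorted by temporal order_index."""
    mine = [m for m in metas if m.patient_id == patient_id]
    if not mine:
        raise KeyError(f"no lesions for patient {patient_id}")
    return [m.lesion_id for m in sorted(mine, key=lambda m: m.order_index)]


# ---------------------------------------------------------------------------
# expression and centroids
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.12g", index_label="gene")


def read_centroids(path) -> pd.DataFrame:
    """Centroid table: genes in rows, one column per subtype label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in SUBTYPES]
    if unknown:
        raise FormatError(f"{path}: unknown subtype columns {unknown}")
    missing = [s for s in SUBTYPES if s not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing subtype columns {missing}")
    return df.astype(float)


def write_centroids(centroids: pd.DataFrame, path) -> None:
    centroids.to_csv(path, sep="\t", float_format="%.12g", index_label="gene")


# ---------------------------------------------------------------------------
# site depths (read support at sites not called in a lesion)
# ---------------------------------------------------------------------------


class SiteDepthTable:
    """Per-lesion sequencing depth and alt support at queried sites.

    Backs the absence calls of the partition step: a variant seen in one
    lesion is declared absent in a sister lesion only when that lesion has
    adequate coverage and near-zero alt fraction at the site.
    """

    def __init__(self, records: Mapping[tuple[str, str, int], tuple[int, int]] | None = None):
        self._records: dict[tuple[str, str, int], tuple[int, int]] = dict(records or {})

    def add(self, lesion_id: str, chrom: str, pos: int, depth: int, alt_reads: int) -> None:
        if depth < 0:
            raise ValueError("negative depth")
        self._records[(lesion_id, chrom, pos)] = (depth, alt_reads)

    def get(self, lesion_id: str, chrom: str, pos: int) -> tuple[int, int] | None:
        return self._records.get((lesion_id, chrom, pos))

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SiteDepthTable) and self._records == other._records

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lesion_id": k[0], "chrom": k[1], "pos": k[2], "depth": v[0], "alt_reads": v[1]}
            for k, v in sorted(self._records.items())
        ]
        cols = ["lesion_id", "chrom", "pos", "depth", "alt_reads"]
        return pd.DataFrame(rows, columns=cols)


def read_site_depths(path) -> SiteDepthTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = SiteDepthTable()
    if df.empty and len(df.columns) <= 1:
        return table
    required = ["lesion_id", "chrom", "pos", "depth", "alt_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing site-depth columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            table.add(row.lesion_id, row.chrom, int(row.pos), int(row.depth), int(row.alt_reads))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return table


def write_site_depths(table: SiteDepthTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference sequence and coding regions
# ---------------------------------------------------------------------------


def open_reference(path):
    """Open a FASTA for random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def get_sequence(reference, chrom: str, start0: int, end0: int) -> str:
    """Slice ``[start0, end0)`` from a pyfaidx Fasta or a plain dict of strings."""
    if start0 < 0:
        raise IndexError(f"negative start {start0}")
    seq = reference[chrom][start0:end0]
    return str(seq).upper()


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open, as BED is defined)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}, line {i}: expected >= 3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}, line {i}: {exc}") from exc
    check_chrom_naming(c for c, _, _ in intervals)
    return intervals


def write_bed(intervals: Sequence[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Knobs shared across subcommands; one seed feeds all randomness."""

    seed: int = 0
    min_depth: int = 20
    max_absent_vaf: float = 0.02
    clonal_tol: float = 0.10
    sv_tolerance_bp: int = 50_000
    sv_mode: str = "either_end"
    sv_merge_window_bp: int = 10_000
    context_halfwidth: int = 5
    n_random_sites: int = 500
    n_permutations: int = 100_000
    variable_gene_fraction: float = 0.75
    min_edge_support: int = 1

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        provided = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **provided)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)
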