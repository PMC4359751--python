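"""Synthetic multi-lesion cohort generator with ground-truth labels.

Plants every structure the pipeline detects, on a small synthetic genome
(a handful of ~100 kb contigs with marked coding blocks):

* a truncal mutation set shared by all of a patient's lesions, an optional
  subset-shared set (on the two later lesions of a 3-lesion patient) and
  lesion-private sets, with configurable sizes (the default 3-lesion
  structure mirrors a heavily diverged third metastasis);
* two substitution processes written INTO the reference sequence so that
  context analyses run on real lookups: a UV-type process (C:G>T:A with a
  5'-pyrimidine bias) and an alternative A:T>G:C process with a biased
  +1/+2 context on the A-normalized strand;
* integer copy-number segments with a shared whole-contig loss, a shared
  interval gain (hosting a two-hit tumour-suppressor scenario with
  multiplicities 1 and 2 at copy number 3) and per-lesion private events;
* VAFs drawn binomially at Poisson depth with success probability
  expected_vaf(m, cn, purity), plus background alt reads at absent sites;
* interchromosomal breakends that do or do not coincide with copy-number
  change points;
* expression profiles drawn around subtype centroids, following a planted
  temporal subtype sequence.

All randomness flows from a single seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clonality import expected_vaf
from .io_formats import (
    SUBTYPES,
    BreakendCall,
    CopyNumberSegment,
    ExpressionMatrix,
    GenomicVariant,
    LesionMeta,
    SegmentIndex,
    SiteDepthTable,
    write_bed,
    write_breakends,
    write_centroids,
    write_expression,
    write_fasta,
    write_metadata,
    write_segments,
    write_site_depths,
    write_variants,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 1
    lesions_per_patient: int = 3
    n_truncal: int = 60
    n_subset_shared: int = 2  # on the two later lesions (3-lesion patients only)
    n_private: tuple[int, ...] = (2, 8, 37)
    truncal_signature: str = "UV"
    subset_signature: str = "UV"
    private_signatures: tuple[str, ...] = ("UV", "UV", "UV")
    # UV process: P(C:G>T:A) and P(pyrimidine immediately 5' of the mutated pyrimidine)
    uv_p_cgta: float = 0.9
    uv_p_5prime_pyrimidine: float = 0.9
    # alternative process: P(A:T>G:C) and the +1/+2 context bias on the A strand
    atgc_p_atgc: float = 0.8
    atgc_context_base: str = "G"
    atgc_context_prob: float = 0.9
    depth_mean: float = 200.0
    purity: float = 1.0
    error_rate: float = 0.001
    p_multiplicity_2_in_gain: float = 0.0  # beyond the planted two-hit pair
    plant_two_hit_gene: bool = True  # RB1-style m=1 + m=2 pair in the shared gain
    n_neutral_breakends: int = 2
    subtype_sequence: tuple[str, ...] | None = None  # default depends on lesion count
    n_genes: int = 200
    n_marker_genes: int = 40
    expression_signal: float = 3.0
    expression_noise_sd: float = 1.5  # 0.5 * signal
    contigs: tuple[tuple[str, int], ...] = (
        ("chr7", 100_000),
        ("chr10", 100_000),
        ("chr13", 100_000),
        ("chr15", 100_000),
    )
    coding_block: int = 500
    coding_gap: int = 500

    def __post_init__(self) -> None:
        if self.lesions_per_patient not in (2, 3):
            raise ValueError("lesions_per_patient must be 2 or 3")
        if len(self.n_private) < self.lesions_per_patient:
            raise ValueError("n_private shorter than lesion count")
        if len(self.private_signatures) < self.lesions_per_patient:
            raise ValueError("private_signatures shorter than lesion count")
        for p in (
            self.uv_p_cgta,
            self.uv_p_5prime_pyrimidine,
            self.atgc_p_atgc,
            self.atgc_context_prob,
            self.error_rate,
            self.p_multiplicity_2_in_gain,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.n_truncal, self.n_subset_shared, *self.n_private) < 0:
            raise ValueError("mutation counts must be >= 0")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity outside (0, 1]")

    @property
    def default_subtype_sequence(self) -> tuple[str, ...]:
        if self.subtype_sequence is not None:
            return self.subtype_sequence[: self.lesions_per_patient]
        if self.lesions_per_patient == 3:
            return ("pigmentation", "proliferative", "proliferative")
        return ("pigmentation", "pigmentation")


def patient1_config(**overrides) -> SimConfig:
    """The heavily diverged 3-lesion structure: 63 truncal, 2 on the later
    pair, privates 2/8/37 with the third lesion under the A:T>G:C process."""
    base = dict(
        n_patients=1,
        lesions_per_patient=3,
        n_truncal=63,
        n_subset_shared=2,
        n_private=(2, 8, 37),
        private_signatures=("UV", "UV", "ATGC"),
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass(frozen=True)
class VariantTruth:
    key: tuple[str, int, str, str]
    patient_id: str
    lesion_set: frozenset[str]
    category: str  # truncal | shared_subset | private
    signature: str
    multiplicity: dict[str, int]  # per present lesion


@dataclass(frozen=True)
class RearrangementTruth:
    chromA: str
    posA: int
    chromB: str
    posB: int
    lesion_set: frozenset[str]
    supported: bool


@dataclass
class SimTruth:
    variants: list[VariantTruth]
    subtype_of_lesion: dict[str, str]
    rearrangements: list[RearrangementTruth]
    tree_counts: dict[str, dict[frozenset, int]]  # patient -> subset -> count

    def category_of(self) -> dict[tuple, str]:
        return {v.key: v.category for v in self.variants}


@dataclass
class SimCohort:
    config: SimConfig
    seed: int
    reference: dict[str, str]
    coding: list[tuple[str, int, int]]
    variants: list[GenomicVariant]
    segments: list[CopyNumberSegment]
    breakends: list[BreakendCall]
    site_depths: SiteDepthTable
    expression: ExpressionMatrix
    centroids: pd.DataFrame
    metas: list[LesionMeta]
    truth: SimTruth

    def lesions_of(self, patient_id: str) -> list[str]:
        mine = sorted(
            (m for m in self.metas if m.patient_id == patient_id),
            key=lambda m: m.order_index,
        )
        return [m.lesion_id for m in mine]

    @property
    def patients(self) -> list[str]:
        seen: list[str] = []
        for m in self.metas:
            if m.patient_id not in seen:
                seen.append(m.patient_id)
        return seen


# ---------------------------------------------------------------------------
# genome and site machinery
# ---------------------------------------------------------------------------


def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        name: _BASES[rng.integers(0, 4, size=length)].copy()
        for name, length in config.contigs
    }


def _coding_intervals(config: SimConfig) -> list[tuple[str, int, int]]:
    out = []
    period = config.coding_block + config.coding_gap
    for name, length in config.contigs:
        start = period  # leave an untouched margin at the contig start
        while start + config.coding_block < length - period:
            out.append((name, start, start + config.coding_block))
            start += period
    return out


_SLOT_WIDTH = 24  # one candidate site per slot keeps >= 13 bp between sites


def _site_slots(coding: Sequence[tuple[str, int, int]]) -> list[tuple[str, int]]:
    """Candidate (chrom, slot_start0) pairs, one potential site per slot."""
    slots = []
    for chrom, start, end in coding:
        for s in range(start, end - _SLOT_WIDTH, _SLOT_WIDTH):
            slots.append((chrom, s))
    return slots


class _SitePool:
    """Draws mutation sites from disjoint slots, optionally region-filtered."""

    def __init__(self, coding, rng: np.random.Generator):
        self.rng = rng
        slots = _site_slots(coding)
        self.order = list(rng.permutation(len(slots)))
        self.slots = slots
        self.used: set[int] = set()

    def draw(self, predicate=None) -> tuple[str, int]:
        for idx in self.order:
            if idx in self.used:
                continue
            chrom, s = self.slots[idx]
            pos0 = s + int(self.rng.integers(6, 18))
            if predicate is None or predicate(chrom, pos0):
                self.used.add(idx)
                return chrom, pos0
        raise ValueError("site pool exhausted: config requests more mutations than coding bases")


def _plant_uv_site(seq: dict[str, np.ndarray], chrom, pos0, config, rng) -> tuple[str, str]:
    """Write a UV-process site into the sequence; returns (ref, alt)."""
    pyr_on_plus = bool(rng.random() < 0.5)
    ref = "C" if pyr_on_plus else "G"
    seq[chrom][pos0] = ref.encode()
    flank0 = pos0 - 1 if pyr_on_plus else pos0 + 1
    if rng.random() < config.uv_p_5prime_pyrimidine:
        fl = "C" if rng.random() < 0.5 else "T"
    else:
        fl = "A" if rng.random() < 0.5 else "G"
    seq[chrom][flank0] = (fl if pyr_on_plus else _COMP[fl]).encode()
    if rng.random() < config.uv_p_cgta:
        alt = "T" if pyr_on_plus else "A"  # C:G>T:A
    elif rng.random() < 0.5:
        alt = "A" if pyr_on_plus else "T"  # C:G>A:T
    else:
        alt = "G" if pyr_on_plus else "C"  # C:G>G:C
    return ref, alt


def _plant_atgc_site(seq: dict[str, np.ndarray], chrom, pos0, config, rng) -> tuple[str, str]:
    """Write an A:T>G:C-process site with its +1/+2 context bias."""
    a_on_plus = bool(rng.random() < 0.5)
    ref = "A" if a_on_plus else "T"
    seq[chrom][pos0] = ref.encode()
    bias = config.atgc_context_base
    others = [b for b in "ACGT" if b != bias]
    for rel in (1, 2):  # +1/+2 on the A-normalized strand
        if rng.random() < config.atgc_context_prob:
            b = bias
        else:
            b = others[int(rng.integers(0, 3))]
        if a_on_plus:
            seq[chrom][pos0 + rel] = b.encode()
        else:
            seq[chrom][pos0 - rel] = _COMP[b].encode()
    if rng.random() < config.atgc_p_atgc:
        alt = "G" if a_on_plus else "C"  # A:T>G:C
    elif rng.random() < 0.5:
        alt = "T" if a_on_plus else "A"  # A:T>T:A
    else:
        alt = "C" if a_on_plus else "G"  # A:T>C:G
    return ref, alt


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, seed: int) -> SimCohort:
    rng = np.random.default_rng(seed)
    seq = _random_genome(config, rng)
    coding = _coding_intervals(config)
    pool = _SitePool(coding, rng)

    contig_names = [c for c, _ in config.contigs]
    loss_contig = contig_names[1]  # whole-contig hemizygous loss, shared
    gain_contig = contig_names[2]  # shared interval gain (copy number 3)
    gain_len = dict(config.contigs)[gain_contig]
    gain_iv = (int(0.3 * gain_len), int(0.6 * gain_len))
    private_cn_contig = contig_names[0]

    variants: list[GenomicVariant] = []
    segments: list[CopyNumberSegment] = []
    breakends: list[BreakendCall] = []
    site_depths = SiteDepthTable()
    metas: list[LesionMeta] = []
    truth_variants: list[VariantTruth] = []
    truth_rearr: list[RearrangementTruth] = []
    tree_counts: dict[str, dict[frozenset, int]] = {}
    subtype_truth: dict[str, str] = {}

    k = config.lesions_per_patient
    subtype_seq = config.default_subtype_sequence

    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        lesions = [f"{pid}_M{i + 1}" for i in range(k)]
        for i, lesion in enumerate(lesions):
            metas.append(
                LesionMeta(
                    patient_id=pid,
                    lesion_id=lesion,
                    order_index=i + 1,
                    site="lymph_node" if i < k - 1 else "subcutaneous",
                    purity=config.purity,
                    ploidy=2.0,
                    subtype_label=subtype_seq[i],
                )
            )
            subtype_truth[lesion] = subtype_seq[i]

        seg_list, priv_bounds = _build_segments(
            config, lesions, loss_contig, gain_contig, gain_iv, private_cn_contig
        )
        segments.extend(seg_list)
        seg_index = SegmentIndex(seg_list)

        # --- mutation sets -------------------------------------------------
        sets: list[tuple[frozenset[str], str, int, str]] = []
        sets.append((frozenset(lesions), config.truncal_signature, config.n_truncal, "truncal"))
        if k == 3 and config.n_subset_shared:
            sets.append(
                (
                    frozenset(lesions[1:]),
                    config.subset_signature,
                    config.n_subset_shared,
                    "shared_subset",
                )
            )
        for i, lesion in enumerate(lesions):
            sets.append(
                (frozenset([lesion]), config.private_signatures[i], config.n_private[i], "private")
            )

        tree_counts[pid] = {s: n for s, _, n, _ in sets if n > 0}

        planted_special = 0
        for lesion_set, signature, n_mut, category in sets:
            for j in range(n_mut):
                gene, effect, predicate, forced_m = "", "", None, None
                if category == "truncal" and config.plant_two_hit_gene and j < 2:
                    # two-hit tumour suppressor inside the shared gain (CN 3)
                    gene = "RB1"
                    effect = "nonsense" if j == 0 else "splice_site"
                    forced_m = 1 if j == 0 else 2
                    predicate = lambda c, q: c == gain_contig and gain_iv[0] + 20 <= q < gain_iv[1] - 20
                elif category == "truncal" and j == 2:
                    gene, effect = "BRAF", "missense"
                elif category == "shared_subset" and j == 0:
                    gene, effect = "PIK3CA", "missense"
                elif category == "private" and lesion_set == frozenset([lesions[-1]]) and j == 0:
                    # defining hit on the hemizygously lost contig
                    gene, effect = "PTEN", "splice_site"
                    predicate = lambda c, q: c == loss_contig

                chrom, pos0 = pool.draw(predicate)
                if signature == "UV":
                    ref, alt = _plant_uv_site(seq, chrom, pos0, config, rng)
                elif signature == "ATGC":
                    ref, alt = _plant_atgc_site(seq, chrom, pos0, config, rng)
                else:
                    raise ValueError(f"unknown signature {signature!r}")
                if not effect:
                    effect = "missense" if rng.random() < 0.7 else "synonymous"
                pos = pos0 + 1

                multiplicity: dict[str, int] = {}
                for lesion in lesions:
                    cn = seg_index.cn_at(lesion, chrom, pos)
                    if forced_m is not None:
                        m = min(forced_m, max(cn, 1))
                    elif cn is not None and cn >= 3 and rng.random() < config.p_multiplicity_2_in_gain:
                        m = 2
                    else:
                        m = 1
                    multiplicity[lesion] = m

                for lesion in lesions:
                    cn = seg_index.cn_at(lesion, chrom, pos)
                    depth = max(1, int(rng.poisson(config.depth_mean)))
                    if lesion in lesion_set:
                        p_alt = expected_vaf(
                            min(multiplicity[lesion], max(cn or 2, 1)),
                            max(cn or 2, 1),
                            config.purity,
                        )
                        alt_reads = int(rng.binomial(depth, min(p_alt, 1.0)))
                        variants.append(
                            GenomicVariant(
                                patient_id=pid,
                                lesion_id=lesion,
                                chrom=chrom,
                                pos=pos,
                                ref=ref,
                                alt=alt,
                                vaf=alt_reads / depth,
                                depth=depth,
                                alt_reads=alt_reads,
                                gene=gene,
                                effect=effect,
                            )
                        )
                    else:
                        alt_reads = int(rng.binomial(depth, config.error_rate))
                        site_depths.add(lesion, chrom, pos, depth, alt_reads)

                truth_variants.append(
                    VariantTruth(
                        key=(chrom, pos, ref, alt),
                        patient_id=pid,
                        lesion_set=lesion_set,
                        category=category,
                        signature=signature,
                        multiplicity={l: multiplicity[l] for l in lesion_set},
                    )
                )
                planted_special += 1

        # --- breakends -----------------------------------------------------
        breakends.extend(
            _build_breakends(
                config, rng, lesions, gain_contig, gain_iv, private_cn_contig,
                priv_bounds, loss_contig, contig_names, truth_rearr,
            )
        )

    expression, centroids = _build_expression(config, rng, metas)

    reference = {name: arr.tobytes().decode() for name, arr in seq.items()}
    return SimCohort(
        config=config,
        seed=seed,
        reference=reference,
        coding=coding,
        variants=variants,
        segments=segments,
        breakends=breakends,
        site_depths=site_depths,
        expression=expression,
        centroids=centroids,
        metas=metas,
        truth=SimTruth(
            variants=truth_variants,
            subtype_of_lesion=subtype_truth,
            rearrangements=truth_rearr,
            tree_counts=tree_counts,
        ),
    )


def _build_segments(config, lesions, loss_contig, gain_contig, gain_iv, private_cn_contig):
    """Per-lesion segmentations: shared loss + shared gain + private gains."""
    lengths = dict(config.contigs)
    segments: list[CopyNumberSegment] = []
    priv_bounds: dict[str, tuple[int, int]] = {}
    L = lengths[private_cn_contig]
    for i, lesion in enumerate(lesions):
        for contig, length in config.contigs:
            if contig == loss_contig:
                segments.append(CopyNumberSegment(lesion, contig, 0, length, 1))
            elif contig == gain_contig:
                a, b = gain_iv
                segments.append(CopyNumberSegment(lesion, contig, 0, a, 2))
                segments.append(CopyNumberSegment(lesion, contig, a, b, 3))
                segments.append(CopyNumberSegment(lesion, contig, b, length, 2))
            elif contig == private_cn_contig:
                # one private gain per lesion, in disjoint fixed slots
                a = int(0.1 * L) + i * int(0.25 * L)
                b = a + int(0.1 * L)
                priv_bounds[lesion] = (a, b)
                segments.append(CopyNumberSegment(lesion, contig, 0, a, 2))
                segments.append(CopyNumberSegment(lesion, contig, a, b, 3))
                segments.append(CopyNumberSegment(lesion, contig, b, length, 2))
            else:
                segments.append(CopyNumberSegment(lesion, contig, 0, length, 2))
    return segments, priv_bounds


def _build_breakends(
    config, rng, lesions, gain_contig, gain_iv, private_cn_contig,
    priv_bounds, loss_contig, contig_names, truth_rearr,
):
    """One shared supported event, one first-lesion private supported event,
    and copy-number-neutral events that no change point backs up."""
    out: list[BreakendCall] = []
    neutral_contig = contig_names[3]
    neutral_len = dict(config.contigs)[neutral_contig]
    loss_len = dict(config.contigs)[loss_contig]

    # shared: end A at the shared-gain start boundary on every lesion
    posB_shared = int(rng.integers(10_000, neutral_len - 10_000))
    for lesion in lesions:
        jitter = int(rng.integers(-2_000, 2_000))
        out.append(
            BreakendCall(
                lesion_id=lesion,
                chromA=gain_contig,
                posA=gain_iv[0] + 1 + jitter,
                chromB=neutral_contig,
                posB=posB_shared + int(rng.integers(-2_000, 2_000)),
                supporting_reads=int(rng.integers(5, 40)),
            )
        )
    truth_rearr.append(
        RearrangementTruth(
            chromA=gain_contig,
            posA=gain_iv[0] + 1,
            chromB=neutral_contig,
            posB=posB_shared,
            lesion_set=frozenset(lesions),
            supported=True,
        )
    )

    # private to the first lesion: end A at its private-gain boundary
    first = lesions[0]
    a, _ = priv_bounds[first]
    posB_priv = int(rng.integers(10_000, loss_len - 10_000))
    out.append(
        BreakendCall(
            lesion_id=first,
            chromA=private_cn_contig,
            posA=a + 1 + int(rng.integers(-2_000, 2_000)),
            chromB=loss_contig,
            posB=posB_priv,
            supporting_reads=int(rng.integers(5, 40)),
        )
    )
    truth_rearr.append(
        RearrangementTruth(
            chromA=private_cn_contig,
            posA=a + 1,
            chromB=loss_contig,
            posB=posB_priv,
            lesion_set=frozenset([first]),
            supported=True,
        )
    )

    # neutral: both ends on contigs without interior change points
    for _ in range(config.n_neutral_breakends):
        lesion = lesions[int(rng.integers(0, len(lesions)))]
        posA = int(rng.integers(10_000, neutral_len - 10_000))
        posB = int(rng.integers(10_000, loss_len - 10_000))
        out.append(
            BreakendCall(
                lesion_id=lesion,
                chromA=neutral_contig,
                posA=posA,
                chromB=loss_contig,
                posB=posB,
                supporting_reads=int(rng.integers(2, 15)),
            )
        )
        truth_rearr.append(
            RearrangementTruth(
                chromA=neutral_contig,
                posA=posA,
                chromB=loss_contig,
                posB=posB,
                lesion_set=frozenset([lesion]),
                supported=False,
            )
        )
    return out


def _build_expression(config, rng, metas):
    """Block-structured centroids plus Gaussian noise around the planted
    subtype of each lesion."""
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    centroids = pd.DataFrame(7.0, index=pd.Index(genes, name="gene"), columns=list(SUBTYPES))
    for s, subtype in enumerate(SUBTYPES):
        block = slice(s * config.n_marker_genes, (s + 1) * config.n_marker_genes)
        centroids.iloc[block, centroids.columns.get_loc(subtype)] += config.expression_signal
    cols = {}
    for m in metas:
        centre = centroids[m.subtype_label].to_numpy()
        cols[m.lesion_id] = centre + rng.normal(0.0, config.expression_noise_sd, size=len(genes))
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(values), centroids


# ---------------------------------------------------------------------------
# serialization and truth comparison
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimCohort, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out / "variants.tsv",
        "segments": out / "segments.seg",
        "breakends": out / "breakends.bedpe",
        "site_depths": out / "site_depths.tsv",
        "expression": out / "expression.tsv",
        "centroids": out / "centroids.tsv",
        "metadata": out / "metadata.tsv",
        "reference": out / "reference.fa",
        "coding": out / "coding.bed",
        "truth_variants": out / "truth_variants.tsv",
        "truth_lesions": out / "truth_lesions.tsv",
        "truth_rearrangements": out / "truth_rearrangements.tsv",
    }
    write_variants(cohort.variants, paths["variants"])
    write_segments(cohort.segments, paths["segments"])
    write_breakends(cohort.breakends, paths["breakends"])
    write_site_depths(cohort.site_depths, paths["site_depths"])
    write_expression(cohort.expression, paths["expression"])
    write_centroids(cohort.centroids, paths["centroids"])
    write_metadata(cohort.metas, paths["metadata"])
    write_fasta(cohort.reference, paths["reference"])
    write_bed(cohort.coding, paths["coding"])

    rows = [
        {
            "chrom": v.key[0],
            "pos": v.key[1],
            "ref": v.key[2],
            "alt": v.key[3],
            "patient_id": v.patient_id,
            "lesions": ",".join(sorted(v.lesion_set)),
            "category": v.category,
            "signature": v.signature,
            "multiplicity": ",".join(f"{l}:{m}" for l, m in sorted(v.multiplicity.items())),
        }
        for v in cohort.truth.variants
    ]
    pd.DataFrame(rows).to_csv(paths["truth_variants"], sep="\t", index=False)
    pd.DataFrame(
        [{"lesion_id": l, "subtype": s} for l, s in sorted(cohort.truth.subtype_of_lesion.items())]
    ).to_csv(paths["truth_lesions"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chromA": r.chromA,
                "posA": r.posA,
                "chromB": r.chromB,
                "posB": r.posB,
                "lesions": ",".join(sorted(r.lesion_set)),
                "supported": int(r.supported),
            }
            for r in cohort.truth.rearrangements
        ]
    ).to_csv(paths["truth_rearrangements"], sep="\t", index=False)
    return paths


def truth_compare(
    truth: SimTruth,
    patterns=None,
    multiplicity_calls=None,
    trees=None,
    subtype_calls=None,
    supported_calls=None,
) -> dict[str, float]:
    """Recovery metrics of pipeline outputs against planted ground truth.

    Every metric is a fraction in [0, 1]; only metrics whose inputs were
    supplied appear in the result.
    """
    metrics: dict[str, float] = {}

    if patterns is not None:
        truth_cat = truth.category_of()
        got = {p.variant_key: p.category for p in patterns}
        missing = set(truth_cat) - set(got)
        if missing:
            raise ValueError(f"{len(missing)} planted variants absent from patterns")
        hits = sum(got[k] == truth_cat[k] for k in truth_cat)
        metrics["category_accuracy"] = hits / len(truth_cat)

    if multiplicity_calls is not None:
        truth_m = {
            (v.key, lesion): m
            for v in truth.variants
            for lesion, m in v.multiplicity.items()
        }
        scored = [
            (call.m_hat, truth_m[(call.variant_key, call.lesion_id)])
            for call in multiplicity_calls
            if (call.variant_key, call.lesion_id) in truth_m
        ]
        if not scored:
            raise ValueError("no multiplicity calls match planted variants")
        metrics["multiplicity_accuracy"] = sum(a == b for a, b in scored) / len(scored)

    if trees is not None:
        from .progression import topology

        ok = 0
        for pid, tree in trees.items():
            planted = truth.tree_counts[pid]
            planted_topology = {
                s for s in planted if 1 < len(s) < len(tree.lesions)
            }
            counts_ok = all(
                tree.edge_count(s) == n
                for s, n in planted.items()
            )
            ok += topology(tree) == planted_topology and counts_ok and not tree.incompatible_patterns
        metrics["tree_recovery"] = ok / len(trees)

    if subtype_calls is not None:
        scored = [
            (c.assigned, truth.subtype_of_lesion[c.lesion_id])
            for c in subtype_calls
            if c.lesion_id in truth.subtype_of_lesion
        ]
        if not scored:
            raise ValueError("no subtype calls match planted lesions")
        metrics["subtype_accuracy"] = sum(a == b for a, b in scored) / len(scored)

    if supported_calls is not None:
        truth_support = {
            (r.chromA, r.chromB, lesion): r.supported
            for r in truth.rearrangements
            for lesion in r.lesion_set
        }
        scored = []
        for sr in supported_calls:
            ca, cb = sorted([sr.call.chromA, sr.call.chromB])
            key = (ca, cb, sr.call.lesion_id)
            if key in truth_support:
                scored.append((sr.supported, truth_support[key]))
        if not scored:
            raise ValueError("no supported-rearrangement calls match planted events")
        metrics["sv_support_accuracy"] = sum(a == b for a, b in scored) / len(scored)

    return metrics
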