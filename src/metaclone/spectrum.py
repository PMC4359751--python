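"""Substitution spectra and flanking sequence-context tests.

Substitutions are tallied in strand-symmetric pair notation (C:G>T:A,
A:T>G:C, ...). A C:G>T:A event with a pyrimidine immediately 5' of the
mutated pyrimidine is the hallmark of UV-induced damage; the
``five_prime_pyrimidine_fraction`` quantifies it.

The window composition test compares, position by position across a
window of +-k flanking bases, the base composition around mutated A/T
sites against randomly sampled coding A/T sites. Each position gives a
4x2 contingency table (bases x site group) tested with a Monte-Carlo
exact test: with both margins fixed, the permutation null of the mutated
column is multivariate hypergeometric, so the null chi-square statistic
is sampled directly. P-values are Benjamini-Hochberg adjusted across the
2k positions.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicVariant, get_sequence

logger = logging.getLogger("metaclone")

PAIR_CLASSES = (
    "C:G>T:A",
    "C:G>A:T",
    "C:G>G:C",
    "A:T>G:C",
    "A:T>T:A",
    "A:T>C:G",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_PYRIMIDINE_CLASS = {
    ("C", "T"): "C:G>T:A",
    ("C", "A"): "C:G>A:T",
    ("C", "G"): "C:G>G:C",
    ("T", "C"): "A:T>G:C",
    ("T", "A"): "A:T>T:A",
    ("T", "G"): "A:T>C:G",
}

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-symmetric pair-notation class of a single-base substitution."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref == alt")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == "N" or alt == "N":
        raise ValueError(f"non-ACGT substitution: {ref}>{alt}")
    if ref in "AG":  # purine ref: read the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return _PYRIMIDINE_CLASS[(ref, alt)]


@dataclass(frozen=True)
class SpectrumProfile:
    counts: dict[str, int]
    n_total: int
    fractions: dict[str, float]
    five_prime_pyrimidine_fraction: float | None  # None when no C:G>T:A site had a flank
    n_ref_mismatch: int = 0


def spectrum_profile(
    variants: Sequence[GenomicVariant],
    reference,
    max_mismatch_rate: float = 0.05,
) -> SpectrumProfile:
    """Pair-notation spectrum of SNVs with the 5'-pyrimidine UV fraction.

    Variants whose stated ref base disagrees with the reference sequence
    are dropped with a warning; a mismatch rate above ``max_mismatch_rate``
    aborts (wrong genome build). The 5' flank of a C:G>T:A site is read on
    the strand where the mutated base is the pyrimidine: for a G ref the
    flank is the complement of the base at pos + 1.
    """
    counts = {c: 0 for c in PAIR_CLASSES}
    n_checked = 0
    n_mismatch = 0
    n_uv = 0
    n_uv_5prime_pyr = 0
    n_uv_with_flank = 0
    for v in variants:
        if not v.is_snv:
            continue
        n_checked += 1
        ref_base = get_sequence(reference, v.chrom, v.pos - 1, v.pos)
        if ref_base != v.ref:
            n_mismatch += 1
            logger.warning(
                "reference mismatch at %s:%d (variant ref %s, sequence %s); dropped",
                v.chrom,
                v.pos,
                v.ref,
                ref_base,
            )
            continue
        cls = classify_substitution(v.ref, v.alt)
        counts[cls] += 1
        if cls == "C:G>T:A":
            n_uv += 1
            flank = _five_prime_flank(reference, v)
            if flank is not None:
                n_uv_with_flank += 1
                if flank in ("C", "T"):
                    n_uv_5prime_pyr += 1
    if n_checked and n_mismatch / n_checked > max_mismatch_rate:
        raise ValueError(
            f"reference mismatch rate {n_mismatch}/{n_checked} exceeds "
            f"{max_mismatch_rate:.0%}: wrong genome build?"
        )
    n_total = sum(counts.values())
    fractions = {c: (counts[c] / n_total if n_total else 0.0) for c in PAIR_CLASSES}
    return SpectrumProfile(
        counts=counts,
        n_total=n_total,
        fractions=fractions,
        five_prime_pyrimidine_fraction=(
            n_uv_5prime_pyr / n_uv_with_flank if n_uv_with_flank else None
        ),
        n_ref_mismatch=n_mismatch,
    )


def _five_prime_flank(reference, v: GenomicVariant) -> str | None:
    """Base 5' of the mutated base on the pyrimidine-normalized strand."""
    if v.ref in "CT":
        if v.pos < 2:
            return None
        return get_sequence(reference, v.chrom, v.pos - 2, v.pos - 1)
    flank = get_sequence(reference, v.chrom, v.pos, v.pos + 1)
    return _COMPLEMENT.get(flank) if flank else None


def sample_coding_AT_sites(
    reference,
    coding_intervals: Sequence[tuple[str, int, int]],
    n: int = 500,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str]]:
    """Uniform sample (without replacement) of n coding A/T sites.

    Intervals are 0-based half-open (BED); returned positions are 1-based
    with the base at each site. Reproducible for a given Generator state.
    """
    if not coding_intervals:
        raise ValueError("no coding intervals supplied")
    rng = rng or np.random.default_rng()
    sites: list[tuple[str, int, str]] = []
    for chrom, start, end in coding_intervals:
        seq = get_sequence(reference, chrom, start, end)
        arr = np.frombuffer(seq.encode(), dtype="S1")
        at_mask = (arr == b"A") | (arr == b"T")
        for off in np.flatnonzero(at_mask):
            sites.append((chrom, start + int(off) + 1, seq[off]))
    if len(sites) < n:
        raise ValueError(f"only {len(sites)} coding A/T sites available, need {n}")
    idx = rng.choice(len(sites), size=n, replace=False)
    return [sites[i] for i in sorted(idx)]


@dataclass(frozen=True)
class ContextTestResult:
    k: int
    positions: tuple[int, ...]  # -k..-1, +1..+k
    mutated_composition: np.ndarray  # (2k, 4) counts over BASES
    random_composition: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    n_mutated: int
    n_random: int
    n_dropped: int
    n_permutations: int

    def p_at(self, position: int, adjusted: bool = True) -> float:
        i = self.positions.index(position)
        return float(self.adjusted_p[i] if adjusted else self.raw_p[i])


def _window(reference, chrom: str, pos: int, k: int) -> str | None:
    """2k+1 bases centred on 1-based pos; None if flanks run off the contig."""
    start = pos - 1 - k
    if start < 0:
        return None
    try:
        seq = get_sequence(reference, chrom, start, pos + k)
    except (IndexError, KeyError):
        return None
    return seq if len(seq) == 2 * k + 1 else None


def _composition(
    reference, sites: Sequence[tuple[str, int]], k: int, orient: str
) -> tuple[np.ndarray, int]:
    """Per-position base counts over a site list; returns (2k x 4, n_dropped)."""
    comp = np.zeros((2 * k, 4), dtype=np.int64)
    dropped = 0
    for chrom, pos in sites:
        win = _window(reference, chrom, pos, k)
        if win is None:
            dropped += 1
            continue
        centre = win[k]
        if centre not in "AT":
            raise ValueError(f"central base {centre!r} at {chrom}:{pos} is not A/T")
        if orient == "A-strand" and centre == "T":
            win = revcomp(win)
        flank = win[:k] + win[k + 1 :]
        for j, base in enumerate(flank):
            if base in _BASE_INDEX:
                comp[j, _BASE_INDEX[base]] += 1
    return comp, dropped


def _mc_composition_p(
    counts1: np.ndarray, counts2: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo exact p for a 4x2 table with both margins fixed.

    The statistic is Pearson chi-square; because the margins are fixed the
    expected counts are identical for every permuted table, and the null
    tables are draws of the group-1 column from a multivariate
    hypergeometric distribution on the pooled base totals.
    """
    n1, n2 = int(counts1.sum()), int(counts2.sum())
    total = counts1 + counts2
    keep = total > 0
    if n1 == 0 or n2 == 0 or keep.sum() < 2:
        return 1.0
    e1 = total[keep] * n1 / (n1 + n2)
    e2 = total[keep] * n2 / (n1 + n2)

    def stat(x1: np.ndarray) -> np.ndarray:
        x2 = total[keep] - x1
        return ((x1 - e1) ** 2 / e1).sum(axis=-1) + ((x2 - e2) ** 2 / e2).sum(axis=-1)

    obs = float(stat(counts1[keep].astype(float)))
    draws = rng.multivariate_hypergeometric(total, n1, size=n_perm)[:, keep].astype(float)
    null = stat(draws)
    return (1.0 + int((null >= obs - 1e-12).sum())) / (n_perm + 1.0)


def window_context_test(
    mutated_sites: Sequence[tuple[str, int]],
    random_sites: Sequence[tuple[str, int]],
    reference,
    k: int = 5,
    n_permutations: int = 100_000,
    rng: np.random.Generator | None = None,
    orient: str = "A-strand",
) -> ContextTestResult:
    """Position-wise composition test of mutated vs random A/T site flanks.

    Sites are (chrom, 1-based pos) with an A or T central base. With
    ``orient='A-strand'`` each window is reverse-complemented when its
    centre is T, so position +1 always means 3' of the A; with
    ``'reference-strand'`` windows are read as-is. Sites lacking a full
    +-k flank are dropped (count reported).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not mutated_sites:
        raise ValueError("empty mutated site list")
    if orient not in ("A-strand", "reference-strand"):
        raise ValueError(f"unknown orientation {orient!r}")
    rng = rng or np.random.default_rng()
    mut_comp, mut_dropped = _composition(reference, mutated_sites, k, orient)
    rand_comp, rand_dropped = _composition(reference, random_sites, k, orient)
    if mut_dropped or rand_dropped:
        logger.info(
            "context test dropped %d mutated and %d random sites lacking full flanks",
            mut_dropped,
            rand_dropped,
        )
    positions = tuple(list(range(-k, 0)) + list(range(1, k + 1)))
    raw = np.array(
        [
            _mc_composition_p(mut_comp[j], rand_comp[j], n_permutations, rng)
            for j in range(2 * k)
        ]
    )
    adjusted = multipletests(raw, method="fdr_bh")[1]
    # BH can only raise a p-value
    adjusted = np.maximum(adjusted, raw)
    return ContextTestResult(
        k=k,
        positions=positions,
        mutated_composition=mut_comp,
        random_composition=rand_comp,
        raw_p=raw,
        adjusted_p=adjusted,
        n_mutated=len(mutated_sites) - mut_dropped,
        n_random=len(random_sites) - rand_dropped,
        n_dropped=mut_dropped + rand_dropped,
        n_permutations=n_permutations,
    )


def context_result_to_frame(result: ContextTestResult):
    import pandas as pd

    rows = []
    for i, pos in enumerate(result.positions):
        row = {"position": pos, "raw_p": result.raw_p[i], "adjusted_p": result.adjusted_p[i]}
        for b, base in enumerate(BASES):
            row[f"mutated_{base}"] = int(result.mutated_composition[i, b])
            row[f"random_{base}"] = int(result.random_composition[i, b])
        rows.append(row)
    return pd.DataFrame(rows)
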