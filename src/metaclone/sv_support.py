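"""Copy-number support filtering and cross-lesion sharing of rearrangements.

A low-coverage-genome breakend call is far more credible when it coincides
with a copy-number change point in the same lesion; filtering on that
coincidence sharply reduces the candidate list, at the stated price of
discarding copy-number-neutral rearrangements. Supported events are then
merged across lesions (same chromosome pair, both ends within a merge
window) and categorised truncal/shared/private like point mutations.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .io_formats import BreakendCall, CopyNumberSegment

DEFAULT_TOLERANCE_BP = 50_000
DEFAULT_MERGE_WINDOW_BP = 10_000


@dataclass(frozen=True)
class SupportedRearrangement:
    call: BreakendCall
    support_points: tuple[tuple[str, str, int, int], ...]  # (lesion, chrom, pos, distance)
    min_distance: int | None  # None when no same-chrom change point exists
    supported: bool


@dataclass(frozen=True)
class SharedRearrangement:
    """One merged rearrangement event with its lesion presence pattern."""

    chromA: str
    chromB: str
    posA: int  # representative (first member's) coordinates
    posB: int
    lesions: frozenset[str]
    category: str  # truncal | shared_subset | private
    members: tuple[BreakendCall, ...]


def cn_change_points(
    segments: Sequence[CopyNumberSegment],
) -> list[tuple[str, int]]:
    """Positions where total CN changes between adjacent segments of one lesion.

    Segments must belong to a single lesion and be non-overlapping. The
    change point is placed at the 1-based start of the later segment of
    each unequal-CN adjacent pair (for abutting segments this is the
    shared boundary; a gap still yields one change point there).
    """
    lesions = {s.lesion_id for s in segments}
    if len(lesions) > 1:
        raise ValueError(f"segments span lesions {sorted(lesions)}")
    points: list[tuple[str, int]] = []
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in sorted(by_chrom.items()):
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if a.total_cn != b.total_cn:
                points.append((chrom, b.start + 1))
    return points


def filter_supported(
    breakends: Sequence[BreakendCall],
    change_points_by_lesion: Mapping[str, Sequence[tuple[str, int]]],
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
    mode: str = "either_end",
) -> list[SupportedRearrangement]:
    """Keep breakends whose end(s) lie near a same-lesion CN change point.

    ``mode='either_end'`` requires at least one of the two breakends near
    (within ``tolerance_bp`` of) a change point on its own chromosome;
    ``'both_ends'`` requires both.
    """
    if tolerance_bp <= 0:
        raise ValueError("tolerance_bp must be > 0")
    if mode not in ("either_end", "both_ends"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[SupportedRearrangement] = []
    for call in breakends:
        points = change_points_by_lesion.get(call.lesion_id, [])
        end_distances: list[int | None] = []
        support: list[tuple[str, str, int, int]] = []
        for chrom, pos in ((call.chromA, call.posA), (call.chromB, call.posB)):
            same = [p for c, p in points if c == chrom]
            if not same:
                end_distances.append(None)
                continue
            nearest = min(same, key=lambda p: abs(p - pos))
            d = abs(nearest - pos)
            end_distances.append(d)
            if d <= tolerance_bp:
                support.append((call.lesion_id, chrom, nearest, d))
        distances = [d for d in end_distances if d is not None]
        min_distance = min(distances) if distances else None
        ends_ok = [d is not None and d <= tolerance_bp for d in end_distances]
        supported = any(ends_ok) if mode == "either_end" else all(ends_ok)
        out.append(
            SupportedRearrangement(
                call=call,
                support_points=tuple(support),
                min_distance=min_distance,
                supported=supported,
            )
        )
    return out


def _oriented(call: BreakendCall) -> tuple[str, int, str, int]:
    """Canonical end order: chromosomes sorted by name."""
    if call.chromA <= call.chromB:
        return call.chromA, call.posA, call.chromB, call.posB
    return call.chromB, call.posB, call.chromA, call.posA


def share_rearrangements(
    calls: Sequence[BreakendCall],
    patient_lesions: Sequence[str],
    merge_window_bp: int = DEFAULT_MERGE_WINDOW_BP,
) -> list[SharedRearrangement]:
    """Merge calls into events and derive their lesion presence patterns.

    Two calls are the same event when their chromosome pairs match and
    both (canonically oriented) ends lie within ``merge_window_bp``;
    merging is transitive (union-find), hence independent of input order.
    """
    if merge_window_bp <= 0:
        raise ValueError("merge_window_bp must be > 0")
    lesion_set = set(patient_lesions)
    for c in calls:
        if c.lesion_id not in lesion_set:
            raise ValueError(f"call lesion {c.lesion_id!r} not in {sorted(lesion_set)}")

    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    oriented = [_oriented(c) for c in calls]
    for i in range(n):
        ca, pa, cb, pb = oriented[i]
        for j in range(i + 1, n):
            ca2, pa2, cb2, pb2 = oriented[j]
            if (
                ca == ca2
                and cb == cb2
                and abs(pa - pa2) <= merge_window_bp
                and abs(pb - pb2) <= merge_window_bp
            ):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    events: list[SharedRearrangement] = []
    for members in groups.values():
        members = sorted(members, key=lambda i: (oriented[i], calls[i].lesion_id))
        lesions = frozenset(calls[i].lesion_id for i in members)
        if len(lesions) == len(lesion_set):
            category = "truncal"
        elif len(lesions) == 1:
            category = "private"
        else:
            category = "shared_subset"
        ca, pa, cb, pb = oriented[members[0]]
        events.append(
            SharedRearrangement(
                chromA=ca,
                chromB=cb,
                posA=pa,
                posB=pb,
                lesions=lesions,
                category=category,
                members=tuple(calls[i] for i in members),
            )
        )
    events.sort(key=lambda e: (e.chromA, e.posA, e.chromB, e.posB))
    return events
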