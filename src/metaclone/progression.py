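"""Per-patient progression model: a clone tree from presence patterns.

Nodes are lesion subsets forming a laminar family (any two nested or
disjoint), as a perfect phylogeny on presence/absence requires; the root
is the full lesion set and its edge carries the truncal mutations. Each
fully assessable pattern is assigned to the edge ending at its presence
subset. When two observed subsets cross (perfect-phylogeny violation) the
smaller-count subset's mutations are diverted to ``incompatible_patterns``
rather than silently dropped.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass

from .io_formats import LesionMeta
from .partition import PresencePattern


@dataclass
class CloneTree:
    patient_id: str
    lesions: tuple[str, ...]
    nodes: list[frozenset]  # includes the root (full set)
    parent: dict[frozenset, frozenset | None]  # root maps to None
    edge_mutations: dict[frozenset, list[tuple]]  # node -> keys on its incoming edge
    incompatible_patterns: list[PresencePattern]

    @property
    def root(self) -> frozenset:
        return frozenset(self.lesions)

    def edge_count(self, subset: frozenset) -> int:
        return len(self.edge_mutations.get(subset, []))

    def children(self, subset: frozenset) -> list[frozenset]:
        return sorted(
            (n for n, p in self.parent.items() if p == subset),
            key=lambda s: (-len(s), sorted(s)),
        )


def _is_laminar_with(subset: frozenset, accepted: Sequence[frozenset]) -> bool:
    return all(
        subset <= other or other <= subset or not (subset & other) for other in accepted
    )


def build_clone_tree(
    patterns: Sequence[PresencePattern],
    lesions: Sequence[str],
    min_edge_support: int = 1,
) -> CloneTree:
    """Construct the clone tree for one patient.

    Patterns categorised unassessable are ignored. Subsets are admitted in
    decreasing mutation-count order (ties broken by lexicographic lesion
    order) subject to laminarity with the already-accepted family; an
    internal (non-root, non-singleton) subset additionally needs
    ``min_edge_support`` mutations. Rejected subsets' patterns land in
    ``incompatible_patterns``.
    """
    if len(lesions) < 2:
        raise ValueError("a clone tree needs >= 2 lesions")
    root = frozenset(lesions)
    patient_ids = {p.patient_id for p in patterns}
    if len(patient_ids) > 1:
        raise ValueError(f"patterns span patients {sorted(patient_ids)}")
    patient_id = patient_ids.pop() if patient_ids else ""

    groups: dict[frozenset, list[PresencePattern]] = {}
    for p in patterns:
        if p.category == "unassessable":
            continue
        subset = p.present_lesions
        if not subset:
            continue
        groups.setdefault(subset, []).append(p)

    ranked = sorted(
        groups,
        key=lambda s: (-len(groups[s]), sorted(s)),
    )
    accepted: list[frozenset] = [root]
    incompatible: list[PresencePattern] = []
    edge_mutations: dict[frozenset, list[tuple]] = {root: []}
    for subset in ranked:
        if subset == root:
            edge_mutations[root] = [p.variant_key for p in groups[subset]]
            continue
        is_internal = len(subset) > 1
        if is_internal and len(groups[subset]) < min_edge_support:
            incompatible.extend(groups[subset])
            continue
        if _is_laminar_with(subset, accepted):
            accepted.append(subset)
            edge_mutations[subset] = [p.variant_key for p in groups[subset]]
        else:
            incompatible.extend(groups[subset])

    # singleton leaves are always nodes, even without private mutations
    for lesion in lesions:
        leaf = frozenset([lesion])
        if leaf not in accepted:
            accepted.append(leaf)
            edge_mutations.setdefault(leaf, [])

    parent: dict[frozenset, frozenset | None] = {root: None}
    for subset in accepted:
        if subset == root:
            continue
        supersets = [s for s in accepted if subset < s]
        parent[subset] = min(supersets, key=len)

    return CloneTree(
        patient_id=patient_id,
        lesions=tuple(lesions),
        nodes=sorted(accepted, key=lambda s: (-len(s), sorted(s))),
        parent=parent,
        edge_mutations=edge_mutations,
        incompatible_patterns=incompatible,
    )


def render_progression(
    tree: CloneTree,
    metas: Sequence[LesionMeta] | None = None,
    treatments: Sequence[tuple[str, str]] | None = None,
    notable_genes: dict[frozenset, list[str]] | None = None,
) -> str:
    """Linearised textual progression model, leaves in temporal order."""
    order = {m.lesion_id: m.order_index for m in metas or []}
    lines = [f"Progression model for patient {tree.patient_id or '?'}"]

    def label(subset: frozenset) -> str:
        members = sorted(subset, key=lambda l: (order.get(l, 0), l))
        return "{" + ",".join(members) + "}"

    def walk(subset: frozenset, depth: int) -> None:
        genes = (notable_genes or {}).get(subset, [])
        gene_note = f" [{', '.join(genes)}]" if genes else ""
        kind = "precursor" if subset == tree.root else ("lesion" if len(subset) == 1 else "subclone")
        lines.append(
            f"{'  ' * depth}{label(subset)} <- {tree.edge_count(subset)} mutations"
            f" ({kind}){gene_note}"
        )
        for child in sorted(
            tree.children(subset),
            key=lambda s: (min(order.get(l, 0) for l in s), sorted(s)),
        ):
            walk(child, depth + 1)

    walk(tree.root, 0)
    for lesion, event in treatments or []:
        lines.append(f"treatment before {lesion}: {event}")
    if tree.incompatible_patterns:
        lines.append(f"CONFLICTS: {len(tree.incompatible_patterns)} pattern(s) violate a")
        lines.append("perfect phylogeny and were excluded from the tree:")
        for p in tree.incompatible_patterns:
            lines.append(f"  {p.variant_key} present in {sorted(p.present_lesions)}")
    return "\n".join(lines)


def tree_to_dot(tree: CloneTree) -> str:
    """Graphviz DOT rendering of the clone tree."""
    def node_id(subset: frozenset) -> str:
        return "n_" + "_".join(sorted(subset))

    lines = ["digraph progression {", "  rankdir=LR;"]
    # virtual origin so the truncal (root-edge) count is visible
    lines.append('  origin [label="normal" shape=point];')
    lines.append(
        f'  origin -> {node_id(tree.root)} [label="{tree.edge_count(tree.root)}"];'
    )
    for subset in tree.nodes:
        shape = "ellipse" if len(subset) > 1 else "box"
        lines.append(
            f'  {node_id(subset)} [label="{{{",".join(sorted(subset))}}}" shape={shape}];'
        )
    for subset, par in tree.parent.items():
        if par is not None:
            lines.append(
                f'  {node_id(par)} -> {node_id(subset)} [label="{tree.edge_count(subset)}"];'
            )
    lines.append("}")
    return "\n".join(lines)


def tree_to_json(tree: CloneTree) -> str:
    payload = {
        "patient_id": tree.patient_id,
        "lesions": list(tree.lesions),
        "edges": [
            {
                "node": sorted(subset),
                "parent": sorted(par) if par is not None else None,
                "n_mutations": tree.edge_count(subset),
                "mutations": [list(k) for k in tree.edge_mutations.get(subset, [])],
            }
            for subset, par in sorted(
                tree.parent.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
            )
        ],
        "incompatible": [
            {"key": list(p.variant_key), "present_in": sorted(p.present_lesions)}
            for p in tree.incompatible_patterns
        ],
    }
    return json.dumps(payload, indent=2)


def topology(tree: CloneTree) -> set[frozenset]:
    """Non-trivial internal subsets (excluding root and singletons)."""
    return {s for s in tree.nodes if 1 < len(s) < len(tree.lesions)}
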