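"""Blocks of Mutations: connected components of the SNV/fragment multigraph.

Every SNV is a vertex; an edge joins two SNVs whenever at least one fragment
holds a known (mutant or non-mutant) status at both — an UNKNOWN end never
links. A Block of Mutations (BM) is a maximal connected component with at
least two members: a group of SNVs whose mutual phase is determined by
direct fragment co-observation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .io_models import SNV
from .read_evidence import FragmentEvidence, SiteStatus


@dataclass
class MutationGraph:
    """SNV multigraph. ``vertices`` is in genomic order; each edge maps the
    (genomically ordered) uid pair to the set of supporting fragment ids."""

    vertices: list[str]
    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {uid: i for i, uid in enumerate(self.vertices)}

    def add_fragment(self, fragment: FragmentEvidence) -> None:
        known = sorted(
            (uid for uid, st in fragment.statuses.items()
             if st is not SiteStatus.UNKNOWN and uid in self._index),
            key=self._index.__getitem__,
        )
        for a, b in combinations(known, 2):
            self.edges.setdefault((a, b), set()).add(fragment.fragment_id)

    def neighbors(self, uid: str) -> list[str]:
        out = [b if a == uid else a for (a, b) in self.edges if uid in (a, b)]
        return sorted(out, key=self._index.__getitem__)


@dataclass
class BlockOfMutations:
    """A maximal fragment-connected group of >=2 SNVs, in genomic order."""

    snvs: list[str]
    fragment_ids: list[str]

    @property
    def bm_id(self) -> str:
        return ";".join(self.snvs)


def build_graph(snvs: Sequence[SNV], fragments: Sequence[FragmentEvidence]) -> MutationGraph:
    """Add, per fragment, an edge between every pair of SNVs at which it holds
    a known status. Vertices with no edges remain isolated."""
    ordered = sorted(snvs, key=lambda s: s.sort_key)
    graph = MutationGraph([s.uid for s in ordered])
    for frag in fragments:
        graph.add_fragment(frag)
    return graph


def find_blocks(graph: MutationGraph) -> list[BlockOfMutations]:
    """Extract BMs as connected components of size >= 2 via depth-first search.

    Components are emitted in genomic order of their first SNV; member lists
    are in genomic order; singleton vertices are not BMs. Output is invariant
    to fragment iteration order.
    """
    adjacency: dict[str, set[str]] = {uid: set() for uid in graph.vertices}
    for a, b in graph.edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    index = graph._index
    seen: set[str] = set()
    blocks: list[BlockOfMutations] = []
    for start in graph.vertices:
        if start in seen or not adjacency[start]:
            continue
        stack = [start]
        component: set[str] = set()
        while stack:
            uid = stack.pop()
            if uid in seen:
                continue
            seen.add(uid)
            component.add(uid)
            stack.extend(sorted(adjacency[uid] - seen, key=index.__getitem__, reverse=True))
        members = sorted(component, key=index.__getitem__)
        support: set[str] = set()
        for pair, frag_ids in graph.edges.items():
            if pair[0] in component:  # edges never leave a component
                support |= frag_ids
        blocks.append(BlockOfMutations(members, sorted(support)))
    return blocks
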