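"""Reconstruction of CRISPR array fragments from spacer adjacency.

Amplicons spanning several repeat-spacer units reveal which spacers sit
next to each other in an array.  Consecutive spacer pairs (and triplets)
from multi-spacer reads are accumulated into a directed adjacency graph
whose edges carry read support; low-support edges (default < 2 reads)
are pruned as likely PCR/sequencing chimeras.  Maximal unambiguous
chains through the pruned graph become array fragments; a branching
node is traversed only when a spacer triplet uniquely phases the path
through it.  Leader-end labelling is purely comparative (the end showing
turnover between samples), never inferred from sequence context.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .cluster import spacers_match
from .extract import SpacerObservation


@dataclass
class AdjacencyGraph:
    """Directed spacer-adjacency evidence: pair and triple support counts."""

    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    triples: dict[tuple[str, str, str], int] = field(default_factory=dict)
    self_loops: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        ns = set()
        for a, b in self.edges:
            ns.add(a)
            ns.add(b)
        return ns


@dataclass
class ArrayFragment:
    """An ordered run of spacer cluster ids with per-junction read support."""

    fragment_id: str
    type_label: str
    spacers: tuple[str, ...]
    junction_support: tuple[int, ...]
    samples: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.spacers) < 2:
            raise ValueError("a fragment needs >= 2 spacers")
        if len(self.junction_support) != len(self.spacers) - 1:
            raise ValueError("junction support must cover every consecutive pair")

    def __len__(self) -> int:
        return len(self.spacers)


def build_adjacency(
    observations: Iterable[SpacerObservation],
    cluster_of: Mapping[str, str],
    min_support: int = 2,
) -> AdjacencyGraph:
    """Accumulate pair/triple adjacency from multi-spacer reads.

    ``cluster_of`` maps spacer sequence -> cluster id (observations whose
    sequence has no cluster, e.g. filtered noise, are skipped).  Edges
    with support below ``min_support`` are pruned; triples are kept only
    while both their flanking pairs survive.
    """
    per_read: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for o in observations:
        cid = cluster_of.get(o.sequence)
        if cid is not None:
            per_read[o.source_id].append((o.index_in_source, cid))
    pair_counts: Counter = Counter()
    triple_counts: Counter = Counter()
    loops: set[str] = set()
    for _read, items in per_read.items():
        items.sort()
        chain = [cid for idx, cid in items]
        idxs = [idx for idx, _cid in items]
        for k in range(len(chain) - 1):
            if idxs[k + 1] != idxs[k] + 1:
                continue  # non-consecutive after filtering: no adjacency claim
            a, b = chain[k], chain[k + 1]
            if a == b:
                loops.add(a)
            pair_counts[(a, b)] += 1
        for k in range(len(chain) - 2):
            if idxs[k + 1] == idxs[k] + 1 and idxs[k + 2] == idxs[k] + 2:
                triple_counts[(chain[k], chain[k + 1], chain[k + 2])] += 1
    edges = {e: c for e, c in pair_counts.items() if c >= min_support and e[0] != e[1]}
    triples = {
        t: c
        for t, c in triple_counts.items()
        if (t[0], t[1]) in edges and (t[1], t[2]) in edges
    }
    return AdjacencyGraph(edges=edges, triples=triples, self_loops=sorted(loops))


def _break_cycles(g: nx.DiGraph) -> list[tuple[str, str]]:
    """Remove the lowest-support edge of every remaining cycle."""
    removed = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return removed
        worst = min(cycle, key=lambda e: (g.edges[e[0], e[1]]["support"], e))
        g.remove_edge(worst[0], worst[1])
        removed.append((worst[0], worst[1]))


def assemble_fragments(
    graph: AdjacencyGraph,
    type_label: str = "",
    samples: frozenset = frozenset(),
) -> list[ArrayFragment]:
    """Maximal unambiguous chains through the adjacency graph.

    An edge a->b belongs to a chain when it is the unique successor of
    ``a`` and the unique predecessor of ``b``; branching nodes terminate
    chains.  A triple (A, X, C) whose flanking pairs are each unique
    among the recorded triples phases two chains through the branching
    node X.  Cycles are broken at their lowest-support edge beforehand.
    """
    g = nx.DiGraph()
    for (a, b), c in graph.edges.items():
        g.add_edge(a, b, support=c)
    _break_cycles(g)

    chain_edges = [
        (a, b)
        for a, b in g.edges
        if g.out_degree(a) == 1 and g.in_degree(b) == 1
    ]
    cg = nx.DiGraph(chain_edges)
    chains: list[list[str]] = []
    starts = [n for n in cg.nodes if cg.in_degree(n) == 0]
    for s in sorted(starts):
        path = [s]
        while cg.out_degree(path[-1]) == 1:
            path.append(next(iter(cg.successors(path[-1]))))
        chains.append(path)
    # nodes untouched by any unambiguous edge stand alone (may be phased)
    lone = sorted(set(g.nodes) - set(cg.nodes))
    chains.extend([[n] for n in lone])

    chain_by_end = {ch[-1]: i for i, ch in enumerate(chains)}
    chain_by_start = {ch[0]: i for i, ch in enumerate(chains)}

    # triple phasing through branching nodes
    by_ax: Counter = Counter()
    by_xc: Counter = Counter()
    for (a, x, c) in graph.triples:
        by_ax[(a, x)] += 1
        by_xc[(x, c)] += 1
    phased: list[list[str]] = []
    used: set[int] = set()
    for (a, x, c) in sorted(graph.triples):
        if g.out_degree(x) <= 1 and g.in_degree(x) <= 1:
            continue  # not a branching node; chains already pass through
        if by_ax[(a, x)] != 1 or by_xc[(x, c)] != 1:
            continue
        i = chain_by_end.get(a)
        j = chain_by_start.get(c)
        if i is None or j is None or i == j:
            continue
        phased.append(chains[i] + [x] + chains[j])
        used.add(i)
        used.add(j)
        if [x] in chains:
            used.add(chains.index([x]))

    out_paths = phased + [ch for i, ch in enumerate(chains) if i not in used]
    frags: list[ArrayFragment] = []
    for path in sorted(out_paths):
        if len(path) < 2:
            continue
        support = tuple(
            graph.edges.get((a, b), 0) for a, b in zip(path, path[1:])
        )
        frags.append(
            ArrayFragment(
                fragment_id=f"{type_label or 'frag'}|{len(frags):04d}",
                type_label=type_label,
                spacers=tuple(path),
                junction_support=support,
                samples=samples,
            )
        )
    return frags


@dataclass
class FragmentComparison:
    """Alignment of two array fragments via their longest shared block."""

    classification: str  # identical | end-trimmed | partially-renewed | unrelated
    shared_block: tuple[str, ...]
    offset_a: int
    offset_b: int
    reversed_b: bool
    trimmed_end: str | None = None  # "left" / "right" (in fragment-a orientation)
    n_trimmed: int = 0
    leader_proximal_end: str | None = None


def _lcs_block(
    a: Sequence[str], b: Sequence[str], same: Callable[[str, str], bool]
) -> tuple[int, int, int]:
    """Longest common contiguous block; returns (length, start_a, start_b)."""
    best = (0, 0, 0)
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and same(a[i + k], b[j + k]):
                k += 1
            if k > best[0]:
                best = (k, i, j)
    return best


def compare_fragments(
    fa: ArrayFragment,
    fb: ArrayFragment,
    sequences: Mapping[str, str] | None = None,
    max_mismatch: int = 1,
) -> FragmentComparison:
    """Classify the relationship of two same-type array fragments.

    Spacer equivalence is cluster-id equality, or, when ``sequences``
    maps ids to centre sequences, the fewer-than-two-mismatches rule.
    Both orientations of ``fb`` are tried.  Classes: ``identical``;
    ``end-trimmed`` (one fragment is an end-anchored sub-run of the
    other — spacers lost from one end); ``partially-renewed`` (a shared
    internal block with fragment-specific spacers beyond it);
    ``unrelated`` (no shared spacers).  An end where both fragments
    carry fragment-specific spacers beyond the shared block is labelled
    the putative leader-proximal end (acquisition happens there).
    """
    if sequences is None:
        same = lambda x, y: x == y  # noqa: E731
    else:
        same = lambda x, y: x == y or spacers_match(  # noqa: E731
            sequences[x], sequences[y], max_mismatch
        ) is not None

    a = list(fa.spacers)
    best = None
    for rev in (False, True):
        b = list(reversed(fb.spacers)) if rev else list(fb.spacers)
        k, i, j = _lcs_block(a, b, same)
        if best is None or k > best[0]:
            best = (k, i, j, rev, b)
    k, i, j, rev, b = best
    if k == 0:
        return FragmentComparison("unrelated", (), 0, 0, rev)
    block = tuple(a[i : i + k])
    a_left, a_right = i, len(a) - (i + k)
    b_left, b_right = j, len(b) - (j + k)
    if a_left == a_right == b_left == b_right == 0:
        return FragmentComparison("identical", block, i, j, rev)
    # end-trimmed: shorter fragment fully contained, anchored at one end
    if (a_left or a_right) and not (b_left or b_right):
        longer_left, longer_right = a_left, a_right
        which = "a"
    elif (b_left or b_right) and not (a_left or a_right):
        longer_left, longer_right = b_left, b_right
        which = "b"
    else:
        which = None
    if which is not None and (longer_left == 0 or longer_right == 0):
        end = "right" if longer_right else "left"
        n = longer_left + longer_right
        return FragmentComparison(
            "end-trimmed", block, i, j, rev, trimmed_end=end, n_trimmed=n
        )
    # both fragments extend beyond the block (or the containment is internal)
    leader = None
    if a_left and b_left and not (a_right or b_right):
        leader = "left"
    elif a_right and b_right and not (a_left or b_left):
        leader = "right"
    return FragmentComparison(
        "partially-renewed", block, i, j, rev, leader_proximal_end=leader
    )
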