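"""Identity clustering of spacers and cross-sample spacer matching.

Clustering follows the UCLUST-style greedy centroid scheme: unique
sequences are visited in decreasing read-count order (ties broken
lexicographically) and each either joins the first existing cluster whose
centre it matches at >= the identity threshold (default 0.85, computed
over the shorter sequence with free end gaps) or seeds a new cluster.
Cluster centres are finalised as the most abundant member sequence.

Cross-sample/site/genome comparison treats two centres as the same spacer
when they differ by fewer than two mismatches: Hamming distance <= 1 for
equal lengths, or a best end-gap-free overlap with <= 1 mismatch and a
total overhang of <= 2 nt for unequal lengths.  The number of unique
spacers in a pooled collection is the number of connected components of
the resulting match graph.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .extract import SpacerObservation


@dataclass
class SpacerCluster:
    """A set of near-identical spacer observations with an abundance-ranked
    centre; the unit of all repertoire comparisons."""

    cluster_id: str
    type_label: str
    sample_id: str
    centre_sequence: str
    members: dict[str, int]  # sequence -> read count

    @property
    def size(self) -> int:
        """Total read count over all member sequences."""
        return sum(self.members.values())

    @property
    def n_unique(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SpacerMatchEdge:
    """Two centres identified as the same spacer (fewer than two mismatches)."""

    spacer_a: str
    spacer_b: str
    mismatches: int
    context: str  # within-site | between-site | genome-genome | cross-type


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def endgap_identity(a: str, b: str) -> float:
    """Best ungapped overlap identity with free end gaps.

    Internal gaps are disallowed; terminal overhangs cost nothing.  The
    identity is the maximal number of matching positions over any offset,
    divided by the length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) == len(b):
        best = len(a) - hamming(a, b)
        if best == len(a):
            return 1.0
    else:
        best = 0
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        lo_a = max(0, off)
        hi_a = min(la, off + lb)
        if hi_a <= lo_a:
            continue
        seg_a = a[lo_a:hi_a]
        seg_b = b[lo_a - off : hi_a - off]
        m = sum(x == y for x, y in zip(seg_a, seg_b))
        if m > best:
            best = m
    return best / min(la, lb)


def greedy_cluster(
    observations: Iterable[SpacerObservation],
    threshold: float = 0.85,
    sample_id: str | None = None,
    type_label: str | None = None,
) -> list[SpacerCluster]:
    """Greedy centroid clustering of one sample+type observation set.

    Deterministic: unique sequences processed by (read count desc,
    sequence asc); assignment to the first (oldest) cluster whose centre
    matches.  Permuting the input record order cannot change the result.
    """
    counts: Counter[str] = Counter()
    for o in observations:
        counts[o.sequence] += o.read_support
        if sample_id is None:
            sample_id = o.sample_id
        if type_label is None:
            type_label = o.type_label
    order = sorted(counts, key=lambda s: (-counts[s], s))
    clusters: list[dict[str, int]] = []
    centres: list[str] = []  # seed centres used during assignment
    for seq in order:
        for i, centre in enumerate(centres):
            if endgap_identity(seq, centre) >= threshold:
                clusters[i][seq] = counts[seq]
                break
        else:
            centres.append(seq)
            clusters.append({seq: counts[seq]})
    out: list[SpacerCluster] = []
    for i, members in enumerate(clusters):
        centre = min(members, key=lambda s: (-members[s], s))
        out.append(
            SpacerCluster(
                cluster_id=f"{type_label}|{sample_id}|c{i:05d}",
                type_label=type_label or "",
                sample_id=sample_id or "",
                centre_sequence=centre,
                members=members,
            )
        )
    return out


def cluster_all(
    observations: Iterable[SpacerObservation], threshold: float = 0.85
) -> list[SpacerCluster]:
    """Cluster observations separately for each (sample, type) stratum."""
    strata: dict[tuple[str, str], list[SpacerObservation]] = defaultdict(list)
    for o in observations:
        strata[(o.sample_id, o.type_label)].append(o)
    out: list[SpacerCluster] = []
    for (sample, tlab) in sorted(strata):
        out.extend(
            greedy_cluster(strata[(sample, tlab)], threshold, sample_id=sample, type_label=tlab)
        )
    return out


def filter_clusters(
    clusters: Sequence[SpacerCluster], min_size: int = 11
) -> list[SpacerCluster]:
    """Retain clusters whose total read count reaches ``min_size``.

    The default (11) keeps clusters with *more than 10* reads, the
    abundance filter applied before repertoire comparisons.
    """
    return [c for c in clusters if c.size >= min_size]


def spacers_match(a: str, b: str, max_mismatch: int = 1, max_overhang: int = 2) -> int | None:
    """Mismatch count if two centres count as the same spacer, else None.

    Equal lengths: Hamming distance <= ``max_mismatch``.  Unequal
    lengths: best end-gap-free overlap covering all but <= ``max_overhang``
    total overhanging nucleotides with <= ``max_mismatch`` mismatches.
    """
    if len(a) == len(b):
        d = hamming(a, b)
        return d if d <= max_mismatch else None
    la, lb = len(a), len(b)
    best: int | None = None
    for off in range(-(lb - 1), la):
        lo_a = max(0, off)
        hi_a = min(la, off + lb)
        w = hi_a - lo_a
        if w <= 0:
            continue
        overhang = (la - w) + (lb - w)
        if overhang > max_overhang:
            continue
        mm = sum(
            x != y for x, y in zip(a[lo_a:hi_a], b[lo_a - off : hi_a - off])
        )
        if mm <= max_mismatch and (best is None or mm < best):
            best = mm
    return best


def _overlap_match(a: str, b: str, min_overlap: int = 20, max_mismatch: int = 1) -> bool:
    """Partial-overlap rule used for cross-type comparisons."""
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        lo_a = max(0, off)
        hi_a = min(la, off + lb)
        w = hi_a - lo_a
        if w < min_overlap:
            continue
        mm = sum(x != y for x, y in zip(a[lo_a:hi_a], b[lo_a - off : hi_a - off]))
        if mm <= max_mismatch:
            return True
    return False


@dataclass
class MatchResult:
    """Outcome of cross-set centre matching."""

    edges: list[SpacerMatchEdge]
    cross_type_edges: list[SpacerMatchEdge]
    n_components: int
    component_of: dict[str, int]
    shared_by: Counter  # number of groups -> number of components seen in that many
    components_groups: dict[int, frozenset]

    def n_shared(self, k: int) -> int:
        """Components present in exactly ``k`` groups."""
        return self.shared_by.get(k, 0)


def match_across(
    groups: Mapping[str, Sequence[tuple[str, str, str]]],
    max_mismatch: int = 1,
    context: str = "between-site",
) -> MatchResult:
    """Match cluster centres across groups (samples, sites or genomes).

    ``groups`` maps a group id to (centre_id, sequence, type_label)
    records.  Same-type centres differing by fewer than two mismatches
    are joined; the unique-spacer count is the number of connected
    components of the resulting graph.  Identical-or-overlapping centres
    of *different* types are reported separately as independent
    acquisition candidates, and do not merge components.
    """
    records: list[tuple[str, str, str, str]] = []  # (group, id, seq, type)
    for gid in sorted(groups):
        for cid, seq, tlab in groups[gid]:
            records.append((gid, cid, seq, tlab))
    g = nx.Graph()
    for _gid, cid, _seq, _tlab in records:
        g.add_node(cid)
    edges: list[SpacerMatchEdge] = []
    cross: list[SpacerMatchEdge] = []
    by_type: dict[str, list[tuple[str, str, str]]] = defaultdict(list)
    for gid, cid, seq, tlab in records:
        by_type[tlab].append((gid, cid, seq))
    for tlab, recs in by_type.items():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                gi, ci, si = recs[i]
                gj, cj, sj = recs[j]
                mm = spacers_match(si, sj, max_mismatch)
                if mm is not None:
                    ctx = context if gi != gj else "within-site"
                    edges.append(SpacerMatchEdge(ci, cj, mm, ctx))
                    g.add_edge(ci, cj)
    tlabs = sorted(by_type)
    for a_i in range(len(tlabs)):
        for b_i in range(a_i + 1, len(tlabs)):
            for gi, ci, si in by_type[tlabs[a_i]]:
                for gj, cj, sj in by_type[tlabs[b_i]]:
                    if _overlap_match(si, sj):
                        cross.append(SpacerMatchEdge(ci, cj, -1, "cross-type"))
    comp_of: dict[str, int] = {}
    comp_groups: dict[int, set] = {}
    group_of = {cid: gid for gid, cid, _s, _t in records}
    for k, comp in enumerate(nx.connected_components(g)):
        gset = set()
        for cid in comp:
            comp_of[cid] = k
            gset.add(group_of[cid])
        comp_groups[k] = gset
    shared = Counter(len(gs) for gs in comp_groups.values())
    return MatchResult(
        edges=edges,
        cross_type_edges=cross,
        n_components=len(comp_groups),
        component_of=comp_of,
        shared_by=shared,
        components_groups={k: frozenset(v) for k, v in comp_groups.items()},
    )
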