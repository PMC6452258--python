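"""Protospacer search, PAM inference, locality and strand-bias statistics.

Spacer centres are searched against target genomes (phages, plasmids,
chromosomes) with an ungapped seed-and-extend scheme: exact 8-mer seeds
on both strands, extension to the full spacer length, and a hit is kept
only when identity exceeds 0.85 over the *entire* spacer with no indels
(a 32-mer therefore needs >= 28 matching positions).  Eight nucleotides
upstream and downstream of every hit — reported in protospacer
orientation — feed per-type PAM count matrices and consensus calls.

Strand-bias convention: a hit is counted as lying on the *transcribed
(template) strand* of an overlapping gene when the protospacer strand is
opposite to the gene's coding strand, i.e. the crRNA spacer can base-pair
with the mRNA.  This is the configuration in which transcription-coupled
(type III) interference is active.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import fisher_exact
from .repeats import revcomp

FLANK_LEN = 8


@dataclass(frozen=True)
class ProtospacerHit:
    """An ungapped spacer match in a target genome.

    Coordinates are 0-based half-open on the target's plus strand.
    ``strand`` is ``"+"`` when the spacer matches the plus strand
    directly and ``"-"`` when it matches the reverse complement.
    Flanks are given in protospacer orientation: ``up_flank`` is 5' of
    the protospacer (the canonical PAM side for I-E), truncated flanks
    at contig edges are None.
    """

    spacer_id: str
    type_label: str
    site_id: str
    target_id: str
    strand: str
    start: int
    end: int
    identity: float
    mismatches: int
    up_flank: str | None
    down_flank: str | None


def search_protospacers(
    spacers: Mapping[str, str] | Sequence[tuple[str, str]],
    targets: Mapping[str, str],
    word_size: int = 8,
    min_identity: float = 0.85,
    spacer_types: Mapping[str, str] | None = None,
    spacer_sites: Mapping[str, str] | None = None,
) -> list[ProtospacerHit]:
    """Ungapped seed-and-extend search of spacers in target sequences.

    ``spacers`` maps spacer id -> sequence; ``targets`` maps target id
    -> sequence.  Hits require identity strictly greater than
    ``min_identity`` over the full spacer length and no indels.
    Duplicate hits (same spacer, same locus) are reported once.
    """
    items = spacers.items() if isinstance(spacers, Mapping) else list(spacers)
    types = spacer_types or {}
    sites = spacer_sites or {}
    hits: list[ProtospacerHit] = []
    for target_id in sorted(targets):
        tseq = targets[target_id].upper()
        index = _kmer_index(tseq, word_size)
        for sid, sseq in sorted(items):
            sseq = sseq.upper()
            if len(sseq) < word_size:
                continue
            for strand in ("+", "-"):
                query = sseq if strand == "+" else revcomp(sseq)
                seen: set[int] = set()
                for off in range(len(query) - word_size + 1):
                    seed = query[off : off + word_size]
                    for pos in index.get(seed, ()):
                        start = pos - off
                        if start < 0 or start + len(query) > len(tseq) or start in seen:
                            continue
                        seen.add(start)
                        window = tseq[start : start + len(query)]
                        mm = sum(a != b for a, b in zip(query, window))
                        ident = (len(query) - mm) / len(query)
                        if ident > min_identity:
                            up, down = extract_flanks(tseq, start, start + len(query), strand)
                            hits.append(
                                ProtospacerHit(
                                    sid, types.get(sid, ""), sites.get(sid, ""),
                                    target_id, strand, start, start + len(query),
                                    ident, mm, up, down,
                                )
                            )
    hits.sort(key=lambda h: (h.target_id, h.start, h.strand, h.spacer_id))
    return hits


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def extract_flanks(
    target: str, start: int, end: int, strand: str, flank: int = FLANK_LEN
) -> tuple[str | None, str | None]:
    """8-nt flanks of a hit in protospacer orientation.

    For minus-strand hits the 5' (upstream) flank is the reverse
    complement of the plus-strand sequence *after* the hit.  Flanks
    truncated by a contig edge are returned as None.
    """
    left = target[max(0, start - flank) : start]
    right = target[end : end + flank]
    if strand == "+":
        up, down = left, right
    else:
        up, down = revcomp(right), revcomp(left)
    return (up if len(up) == flank else None, down if len(down) == flank else None)


@dataclass
class PamModel:
    """Per-position nucleotide counts over 8 upstream + 8 downstream flank
    positions, with information content and a degenerate consensus call."""

    type_label: str
    up_counts: pd.DataFrame    # index positions -8..-1, columns ACGT
    down_counts: pd.DataFrame  # index positions +1..+8
    n_hits: int
    up_consensus: str
    down_consensus: str
    up_information: np.ndarray
    down_information: np.ndarray


_TWOFOLD = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def _column_stats(col_counts: np.ndarray) -> tuple[str, float]:
    """Consensus symbol and information content (bits) for one column."""
    n = col_counts.sum()
    if n == 0:
        return "N", 0.0
    p = col_counts / n
    info = 2.0 + sum(pi * math.log2(pi) for pi in p if pi > 0)
    order = np.argsort(-p, kind="stable")
    bases = "ACGT"
    if p[order[0]] >= 0.75:
        sym = bases[order[0]]
    elif p[order[0]] + p[order[1]] >= 0.9:
        sym = _TWOFOLD[frozenset(bases[order[0]] + bases[order[1]])]
    else:
        sym = "N"
    return sym, info


def build_pam(
    hits: Iterable[ProtospacerHit], type_label: str = "", min_hits: int = 5
) -> PamModel:
    """Build a PAM count matrix and consensus from hit flanks.

    Only hits with both flanks intact contribute.  With fewer than
    ``min_hits`` usable flanks the matrix is still returned but no
    consensus is called (all-``n`` lowercase placeholder) and a warning
    is issued.
    """
    bases = "ACGT"
    up = np.zeros((FLANK_LEN, 4), dtype=int)
    down = np.zeros((FLANK_LEN, 4), dtype=int)
    n = 0
    for h in hits:
        if h.up_flank is None or h.down_flank is None:
            continue
        if any(b not in bases for b in h.up_flank + h.down_flank):
            continue
        for j, b in enumerate(h.up_flank):
            up[j, bases.index(b)] += 1
        for j, b in enumerate(h.down_flank):
            down[j, bases.index(b)] += 1
        n += 1
    up_df = pd.DataFrame(up, index=range(-FLANK_LEN, 0), columns=list(bases))
    down_df = pd.DataFrame(down, index=range(1, FLANK_LEN + 1), columns=list(bases))
    if n < min_hits:
        warnings.warn(
            f"only {n} usable flanks for {type_label or 'PAM'}; no consensus called",
            stacklevel=2,
        )
        return PamModel(type_label, up_df, down_df, n, "n" * FLANK_LEN,
                        "n" * FLANK_LEN, np.zeros(FLANK_LEN), np.zeros(FLANK_LEN))
    up_cons, up_info = zip(*(_column_stats(up[j]) for j in range(FLANK_LEN)))
    dn_cons, dn_info = zip(*(_column_stats(down[j]) for j in range(FLANK_LEN)))
    return PamModel(
        type_label, up_df, down_df, n,
        "".join(up_cons), "".join(dn_cons),
        np.array(up_info), np.array(dn_info),
    )


def locality_table(
    hits: Sequence[ProtospacerHit],
    spacer_sites: Mapping[str, str],
    target_site: str,
    target_id: str,
) -> tuple[list[list[int]], float]:
    """2x2 locality test for one target: spacer local/foreign x hit/no-hit.

    ``spacer_sites`` covers the whole spacer collection searched (hit or
    not); a spacer is local when its site equals the target's isolation
    site.  Returns the table [[local_hit, local_nohit],
    [foreign_hit, foreign_nohit]] and the two-sided Fisher p.
    """
    hit_ids = {h.spacer_id for h in hits if h.target_id == target_id}
    local_hit = local_no = foreign_hit = foreign_no = 0
    for sid, site in spacer_sites.items():
        is_local = site == target_site
        is_hit = sid in hit_ids
        if is_local and is_hit:
            local_hit += 1
        elif is_local:
            local_no += 1
        elif is_hit:
            foreign_hit += 1
        else:
            foreign_no += 1
    table = [[local_hit, local_no], [foreign_hit, foreign_no]]
    return table, fisher_exact(table)


def hits_by_site_table(hits: Sequence[ProtospacerHit]) -> pd.DataFrame:
    """Hit counts per spacer site of origin x target (summary layout)."""
    df = pd.DataFrame(
        [{"site": h.site_id, "target": h.target_id} for h in hits]
    )
    if df.empty:
        return df
    return df.pivot_table(index="site", columns="target", aggfunc="size", fill_value=0)


def hits_by_type_table(
    hits: Sequence[ProtospacerHit], pams: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Hit counts per CRISPR type x target, with an optional PAM column."""
    df = pd.DataFrame(
        [{"type": h.type_label, "target": h.target_id} for h in hits]
    )
    if df.empty:
        return df
    out = df.pivot_table(index="type", columns="target", aggfunc="size", fill_value=0)
    if pams:
        out.insert(0, "PAM", [pams.get(t, "") for t in out.index])
    return out


@dataclass(frozen=True)
class Gene:
    """A gene interval on a target (0-based half-open, coding strand)."""

    target_id: str
    start: int
    end: int
    strand: str
    gene_id: str = ""


def read_gff_genes(path) -> list[Gene]:
    """Minimal GFF3 gene/CDS reader (coordinates converted to 0-based)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] not in ("gene", "CDS"):
                continue
            gid = ""
            if len(f) > 8:
                for kv in f[8].split(";"):
                    if kv.startswith("ID="):
                        gid = kv[3:]
            genes.append(Gene(f[0], int(f[3]) - 1, int(f[4]), f[6], gid))
    return genes


def strand_bias(
    hits: Sequence[ProtospacerHit],
    genes: Sequence[Gene],
    min_overlap_frac: float = 0.5,
) -> dict:
    """Fraction of gene-overlapping hits on the transcribed strand.

    A hit is assigned to a gene when >= ``min_overlap_frac`` of the hit
    length overlaps the gene.  The hit lies on the transcribed (template)
    strand when its strand differs from the gene's coding strand — the
    configuration where the crRNA base-pairs with the transcript.  A
    two-sided exact binomial test against 0.5 accompanies the fraction;
    with no assignable hits all values are NaN.
    """
    by_target: dict[str, list[Gene]] = defaultdict(list)
    for g in genes:
        by_target[g.target_id].append(g)
    n_template = 0
    n_total = 0
    for h in hits:
        hlen = h.end - h.start
        for g in by_target.get(h.target_id, ()):
            ov = min(h.end, g.end) - max(h.start, g.start)
            if ov >= min_overlap_frac * hlen:
                n_total += 1
                if h.strand != g.strand:
                    n_template += 1
                break
    if n_total == 0:
        return {"n_hits": 0, "fraction_transcribed": float("nan"), "p_value": float("nan")}
    frac = n_template / n_total
    p = float(sps.binomtest(n_template, n_total, 0.5, alternative="two-sided").pvalue)
    return {"n_hits": n_total, "fraction_transcribed": frac, "p_value": p}
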