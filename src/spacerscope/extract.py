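"""Spacer extraction from amplicon reads and CRISPR array mining from genomes.

A spacer is the sequence between two adjacent direct repeats of the same
CRISPR type.  On amplicon reads the repeats are located approximately
(degenerate consensus, a few mismatches tolerated) and every gap bounded
by two full-length, same-type, same-strand repeat matches whose length
falls inside the expected band for that type is emitted as a spacer
observation.  Reads whose adjacent repeats belong to different types are
flagged as chimera candidates and yield no spacer from that junction.

All spacers are reported in the consensus (+) frame so forward and
reverse reads of the same array produce identical spacer strings, and
``index_in_source`` numbers spacers in array order within each read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .repeats import RepeatConsensus, RepeatMatch, revcomp, scan_for_repeats


@dataclass(frozen=True)
class SpacerObservation:
    """One extracted spacer occurrence, in consensus (+) orientation."""

    sequence: str
    sample_id: str
    site_id: str
    type_label: str
    source_id: str
    index_in_source: int
    read_support: int = 1


@dataclass(frozen=True)
class GenomeArray:
    """A mined CRISPR array: >= 2 repeat copies chained along one strand.

    ``spacers`` are stored in the consensus (+) frame, ordered along the
    array (for minus-strand arrays this is the reverse of genomic order),
    so the array content is invariant to reverse-complementing the contig.
    """

    genome_id: str
    type_label: str
    contig: str
    start: int
    end: int
    spacers: tuple[str, ...]
    repeat_mismatches: tuple[int, ...]
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if len(self.repeat_mismatches) < 2:
            raise ValueError("an array needs at least two repeat copies")
        if len(self.spacers) != len(self.repeat_mismatches) - 1:
            raise ValueError("spacer count must equal repeat count - 1")


@dataclass
class ExtractionStats:
    """Per-run bookkeeping for auditing filter decisions."""

    n_reads: int = 0
    n_spacers: int = 0
    out_of_band_gaps: int = 0
    chimeric_reads: list[str] = field(default_factory=list)
    ambiguous_spacers: int = 0
    flagged_repeat_windows: int = 0


def quality_trim(seq: str, quals: Sequence[int] | None, min_qual: int = 20) -> str:
    """Trim the 3' tail down to the last base with Phred >= ``min_qual``."""
    if quals is None:
        return seq
    if len(quals) != len(seq):
        raise ValueError("quality string length differs from sequence length")
    end = len(seq)
    while end > 0 and quals[end - 1] < min_qual:
        end -= 1
    return seq[:end]


def _repeat_fragment_inside(spacer: str, flank_repeats: Sequence[str], max_mm: int = 1) -> bool:
    """True if an 8-nt terminal fragment of either observed flanking repeat
    occurs inside the spacer with fewer than two mismatches (guard against
    residual repeat sequence contaminating a spacer call)."""
    if len(spacer) < 8:
        return False
    for rep in flank_repeats:
        for frag in (rep[:8], rep[-8:]):
            if len(frag) < 8:
                continue
            for i in range(len(spacer) - 7):
                win = spacer[i : i + 8]
                if sum(a != b for a, b in zip(frag, win)) <= max_mm:
                    return True
    return False


def extract_from_read(
    read_seq: str,
    quals: Sequence[int] | None,
    consensi: Sequence[RepeatConsensus],
    max_mismatch: int = 3,
    min_qual: int = 20,
    sample_id: str = "",
    site_id: str = "",
    source_id: str = "",
    stats: ExtractionStats | None = None,
) -> list[SpacerObservation]:
    """Extract spacers from one read.

    Adjacent same-type, same-strand repeat matches whose gap is inside
    the type's expected spacer-length band bound a spacer.  Junctions
    bounded by different repeat types are dropped and the read flagged
    as a chimera candidate.  Spacers containing ambiguous bases are
    discarded, as are spacers carrying a residual repeat fragment.
    """
    if stats is None:
        stats = ExtractionStats()
    stats.n_reads += 1
    seq = quality_trim(read_seq.upper(), quals, min_qual)
    if not seq:
        return []
    by_type = {c.type_label: c for c in consensi}
    matches: list[RepeatMatch] = []
    for cons in consensi:
        matches.extend(scan_for_repeats(seq, cons, max_mismatch))
    matches.sort(key=lambda r: r.start)
    stats.flagged_repeat_windows += sum(1 for m in matches if m.flagged)

    raw: list[tuple[str, str]] = []  # (spacer in + frame, strand) in read order
    for left, right in zip(matches, matches[1:]):
        if left.type_label != right.type_label:
            if source_id not in stats.chimeric_reads:
                stats.chimeric_reads.append(source_id)
            continue
        if left.strand != right.strand:
            continue
        cons = by_type[left.type_label]
        gap = seq[left.end : right.start]
        lo, hi = cons.spacer_band
        if not (lo <= len(gap) <= hi):
            stats.out_of_band_gaps += 1
            continue
        if "N" in gap:
            stats.ambiguous_spacers += 1
            continue
        if _repeat_fragment_inside(gap, (seq[left.start : left.end], seq[right.start : right.end])):
            continue
        spacer = gap if left.strand == "+" else revcomp(gap)
        raw.append((spacer, left.strand, left.type_label))

    # read order -> array order: minus-strand reads run leader-opposite
    out: list[SpacerObservation] = []
    per_type: dict[str, list[tuple[str, str]]] = {}
    for spacer, strand, tlab in raw:
        per_type.setdefault(tlab, []).append((spacer, strand))
    for tlab, items in per_type.items():
        ordered = items if items[0][1] == "+" else list(reversed(items))
        for idx, (spacer, _strand) in enumerate(ordered):
            out.append(
                SpacerObservation(
                    spacer, sample_id, site_id, tlab, source_id, idx
                )
            )
    stats.n_spacers += len(out)
    return out


def _open_maybe_gz(path):
    p = str(path)
    return gzip.open(p, "rt") if p.endswith(".gz") else open(p)


def extract_fastq(
    fastq_path,
    consensi: Sequence[RepeatConsensus],
    max_mismatch: int = 3,
    min_qual: int = 20,
    sample_id: str = "",
    site_id: str = "",
) -> tuple[list[SpacerObservation], ExtractionStats]:
    """Run :func:`extract_from_read` over a FASTQ file (gzip allowed)."""
    stats = ExtractionStats()
    out: list[SpacerObservation] = []
    with _open_maybe_gz(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.extend(
                extract_from_read(
                    str(rec.seq),
                    rec.letter_annotations.get("phred_quality"),
                    consensi,
                    max_mismatch=max_mismatch,
                    min_qual=min_qual,
                    sample_id=sample_id,
                    site_id=site_id,
                    source_id=rec.id,
                    stats=stats,
                )
            )
    return out, stats


def mine_genome_arrays(
    contigs: dict[str, str],
    consensi: Sequence[RepeatConsensus],
    max_mismatch: int = 3,
    genome_id: str = "",
) -> list[GenomeArray]:
    """Mine complete CRISPR arrays from genome contigs.

    Chains of >= 2 same-type, same-strand repeat matches separated by
    in-band gaps become arrays; spacers are reported in array order in
    the consensus (+) frame.
    """
    arrays: list[GenomeArray] = []
    for contig_id, seq in contigs.items():
        seq = seq.upper()
        for cons in consensi:
            matches = scan_for_repeats(seq, cons, max_mismatch)
            lo, hi = cons.spacer_band
            chain: list[RepeatMatch] = []
            for m in matches + [None]:  # type: ignore[list-item]
                if (
                    chain
                    and m is not None
                    and m.strand == chain[-1].strand
                    and lo <= m.start - chain[-1].end <= hi
                ):
                    chain.append(m)
                    continue
                if len(chain) >= 2:
                    arrays.append(_chain_to_array(seq, chain, cons, genome_id, contig_id))
                chain = [m] if m is not None else []
    arrays.sort(key=lambda a: (a.contig, a.start, a.type_label))
    return arrays


def _chain_to_array(
    seq: str,
    chain: list[RepeatMatch],
    cons: RepeatConsensus,
    genome_id: str,
    contig_id: str,
) -> GenomeArray:
    gaps = [seq[a.end : b.start] for a, b in zip(chain, chain[1:])]
    strand = chain[0].strand
    if strand == "+":
        spacers = tuple(gaps)
        mism = tuple(m.mismatches for m in chain)
    else:
        spacers = tuple(revcomp(g) for g in reversed(gaps))
        mism = tuple(m.mismatches for m in reversed(chain))
    return GenomeArray(
        genome_id=genome_id,
        type_label=cons.type_label,
        contig=contig_id,
        start=chain[0].start,
        end=chain[-1].end,
        spacers=spacers,
        repeat_mismatches=mism,
        orientation=strand,
    )


def mine_fasta(
    fasta_path, consensi: Sequence[RepeatConsensus], max_mismatch: int = 3, genome_id: str = ""
) -> list[GenomeArray]:
    contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not genome_id:
        genome_id = str(fasta_path)
    return mine_genome_arrays(contigs, consensi, max_mismatch, genome_id)


def spacer_length_profile(
    items: Iterable[SpacerObservation] | Iterable[GenomeArray],
) -> pd.DataFrame:
    """Per-type mean/sd of spacer length; the mean is also reported rounded
    to the nearest integer, the convention for repeat-table summaries."""
    rows = []
    for it in items:
        if isinstance(it, GenomeArray):
            rows.extend({"type_label": it.type_label, "length": len(s)} for s in it.spacers)
        else:
            rows.append({"type_label": it.type_label, "length": len(it.sequence)})
    if not rows:
        return pd.DataFrame(columns=["type_label", "n", "mean", "sd", "mean_rounded"])
    df = pd.DataFrame(rows)
    prof = (
        df.groupby("type_label")["length"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    prof["mean_rounded"] = prof["mean"].round().astype(int)
    return prof


def observations_to_frame(obs: Iterable[SpacerObservation]) -> pd.DataFrame:
    """Tabular form of spacer observations (the on-disk TSV schema)."""
    return pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "site_id": o.site_id,
                "type_label": o.type_label,
                "sequence": o.sequence,
                "source_id": o.source_id,
                "index_in_source": o.index_in_source,
                "read_support": o.read_support,
            }
            for o in obs
        ]
    )


def frame_to_observations(df: pd.DataFrame) -> list[SpacerObservation]:
    return [
        SpacerObservation(
            r.sequence,
            str(r.sample_id),
            str(r.site_id),
            r.type_label,
            str(r.source_id),
            int(r.index_in_source),
            int(getattr(r, "read_support", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def write_arrays_gff3(arrays: Sequence[GenomeArray], path) -> None:
    """Arrays as GFF3: one repeat_region feature per array with child
    spacer features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, arr in enumerate(arrays):
            aid = f"array{i:04d}"
            fh.write(
                "\t".join(
                    [
                        arr.contig, "spacerscope", "repeat_region",
                        str(arr.start + 1), str(arr.end), ".",
                        arr.orientation, ".",
                        f"ID={aid};crispr_type={arr.type_label};n_spacers={len(arr.spacers)}",
                    ]
                )
                + "\n"
            )
            for j, sp in enumerate(arr.spacers):
                fh.write(
                    "\t".join(
                        [
                            arr.contig, "spacerscope", "CRISPR_spacer",
                            ".", ".", ".", arr.orientation, ".",
                            f"ID={aid}.s{j};Parent={aid};seq={sp}",
                        ]
                    )
                    + "\n"
                )
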