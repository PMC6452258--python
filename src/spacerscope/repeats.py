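"""Degenerate CRISPR repeat consensi and approximate repeat matching.

A CRISPR direct repeat is summarised as an IUPAC-degenerate consensus
(e.g. ``GTAGTCCCCACRCRYGTGGGGATGGMCSD`` for the type I-E repeat of
*Thermus*).  This module locates approximate occurrences of such a
consensus on both strands of an arbitrary DNA sequence, counting at each
position the number of bases that violate the degenerate class.  Repeat
matches anchor everything downstream: spacers are the gaps between
adjacent same-type matches.

Coordinates are 0-based half-open throughout the library; report writers
convert to 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

# 4-bit encoding: one bit per concrete base, degenerate = union of bits.
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Maximum subject Ns tolerated inside a repeat window before the match is
#: flagged as unreliable (ambiguity-heavy reads are suspect).
MAX_N_IN_WINDOW = 2


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatConsensus:
    """An IUPAC-degenerate repeat consensus for one CRISPR type/subtype.

    Parameters
    ----------
    type_label : str
        CRISPR type or subtype name, e.g. ``"I-E"`` or ``"IIIAB"``.
    sequence : str
        Degenerate DNA consensus of the direct repeat.
    expected_spacer_length : int
        Typical spacer length (nt) for arrays of this type.
    length_tolerance : int
        Half-width of the accepted spacer-length band (nt).
    """

    type_label: str
    sequence: str
    expected_spacer_length: int
    length_tolerance: int = 10

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("repeat consensus sequence must be non-empty")
        bad = set(self.sequence.upper()) - set(IUPAC_BITS)
        if bad:
            raise ValueError(f"non-IUPAC symbols in repeat consensus: {sorted(bad)}")
        if self.expected_spacer_length <= 0:
            raise ValueError("expected_spacer_length must be positive")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be non-negative")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def spacer_band(self) -> tuple[int, int]:
        """Inclusive (min, max) accepted spacer length."""
        return (
            self.expected_spacer_length - self.length_tolerance,
            self.expected_spacer_length + self.length_tolerance,
        )


@dataclass(frozen=True, order=True)
class RepeatMatch:
    """One approximate occurrence of a repeat consensus.

    ``start``/``end`` are 0-based half-open on the scanned (forward)
    sequence regardless of strand.  ``mismatches`` counts pattern
    violations by unambiguous bases; subject ``N``s match any pattern
    symbol but are tallied separately in ``n_count`` and the match is
    ``flagged`` when more than :data:`MAX_N_IN_WINDOW` occur.
    """

    start: int
    end: int
    strand: str
    mismatches: int
    type_label: str = field(compare=False)
    n_count: int = field(default=0, compare=False)

    @property
    def flagged(self) -> bool:
        return self.n_count > MAX_N_IN_WINDOW

    def overlaps(self, other: "RepeatMatch") -> bool:
        return self.start < other.end and other.start < self.end


def iupac_mismatches(pattern: str, window: str) -> int:
    """Count positions of ``window`` violating the degenerate ``pattern``.

    Subject ``N``s are treated as wildcards (0 mismatches).  Raises
    ``ValueError`` on unknown symbols in the pattern or on length
    disagreement.
    """
    if len(pattern) != len(window):
        raise ValueError("pattern and window must have equal length")
    mism = 0
    for p, b in zip(pattern.upper(), window.upper()):
        try:
            pbits = IUPAC_BITS[p]
        except KeyError:
            raise ValueError(f"unknown IUPAC symbol in pattern: {p!r}") from None
        bbits = IUPAC_BITS.get(b, 0)
        if not (pbits & bbits):
            mism += 1
    return mism


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to its 4-bit base masks (unknown symbols -> 0)."""
    table = np.zeros(256, dtype=np.uint8)
    for sym, bits in IUPAC_BITS.items():
        table[ord(sym)] = bits
        table[ord(sym.lower())] = bits
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(
    enc: np.ndarray, is_n: np.ndarray, pattern: str, max_mismatch: int
) -> list[tuple[int, int, int]]:
    """All (start, mismatches, n_count) where pattern fits with <= max_mismatch."""
    m = len(pattern)
    L = enc.shape[0]
    if L < m:
        return []
    nwin = L - m + 1
    mism = np.zeros(nwin, dtype=np.int32)
    ncnt = np.zeros(nwin, dtype=np.int32)
    for j, sym in enumerate(pattern.upper()):
        pbits = IUPAC_BITS[sym]
        col = enc[j : j + nwin]
        mism += (col & pbits) == 0
        ncnt += is_n[j : j + nwin]
    keep = np.flatnonzero(mism <= max_mismatch)
    return [(int(i), int(mism[i]), int(ncnt[i])) for i in keep]


def scan_for_repeats(
    seq: str, consensus: RepeatConsensus, max_mismatch: int = 3
) -> list[RepeatMatch]:
    """Find all occurrences of a repeat consensus on both strands.

    A minus-strand match means the reverse complement of the scanned
    sequence carries the consensus; its coordinates still refer to the
    forward sequence.  Overlapping matches of the same type are resolved
    greedily, keeping the lower-mismatch (then leftmost, then plus-strand)
    one.  Result is sorted by start coordinate.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not seq:
        return []
    enc = _encode(seq)
    is_n = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8) == ord("N")
    m = len(consensus)
    raw: list[RepeatMatch] = []
    for strand, pat in (("+", consensus.sequence), ("-", revcomp(consensus.sequence))):
        for start, mm, nc in _scan_one_strand(enc, is_n, pat, max_mismatch):
            raw.append(
                RepeatMatch(start, start + m, strand, mm, consensus.type_label, nc)
            )
    return resolve_overlaps(raw)


def resolve_overlaps(matches: Iterable[RepeatMatch]) -> list[RepeatMatch]:
    """Greedy non-overlapping subset: mismatches asc, then start, then strand."""
    chosen: list[RepeatMatch] = []
    for cand in sorted(matches, key=lambda r: (r.mismatches, r.start, r.strand)):
        if not any(cand.overlaps(c) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


def scan_all(
    seq: str, consensi: Sequence[RepeatConsensus], max_mismatch: int = 3
) -> dict[str, list[RepeatMatch]]:
    """Scan one sequence against a whole consensus set, keyed by type."""
    return {c.type_label: scan_for_repeats(seq, c, max_mismatch) for c in consensi}


def load_repeat_table(path) -> list[RepeatConsensus]:
    """Read a 4-column TSV (type_label, sequence, expected_spacer_length,
    length_tolerance); a header line is detected and skipped."""
    out: list[RepeatConsensus] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "type_label":
                continue
            if len(row) < 3:
                raise ValueError(f"repeat table row too short: {row}")
            tol = int(row[3]) if len(row) > 3 else 10
            out.append(RepeatConsensus(row[0], row[1], int(row[2]), tol))
    labels = [c.type_label for c in out]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate type labels in repeat table")
    return out


def default_repeats() -> list[RepeatConsensus]:
    """The packaged *Thermus* repeat consensus set (six types/subtypes)."""
    ref = resources.files("spacerscope") / "data" / "repeats_default.tsv"
    with resources.as_file(ref) as path:
        return load_repeat_table(path)
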