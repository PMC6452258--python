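"""Ground-truthed synthetic thermophile communities, phages and reads.

The generator emulates the statistical structure a repeat-anchored
spacer survey sees in the field: several samples per hot-spring site;
per-site spacer repertoires with a heavy-tailed (log-normal) strain
abundance distribution; CRISPR arrays of 10-35 spacers partially shared
across sites, with site-specific spacers added at the leader-proximal
end and occasional loss at the leader-distal end; phage genomes carrying
protospacers flanked by type-specific PAMs, drawn preferentially from
the phage's home site; and amplicon reads spanning 1-4 repeat-spacer
units with substitution errors.

Every planted feature is recorded in a :class:`CommunityTruth` object
that serialises to JSON next to the generated FASTA/FASTQ, so each
pipeline stage can be scored against known truth.  All randomness flows
from a single integer seed; identical seed and config give
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .repeats import IUPAC_BITS, RepeatConsensus, revcomp, default_repeats

_BASES = "ACGT"
_BITS_TO_BASES = {
    bits: [b for b in _BASES if IUPAC_BITS[b] & bits] for bits in range(1, 16)
}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def instantiate_repeat(rng: np.random.Generator, consensus: str) -> str:
    """Replace degenerate symbols with concrete bases, uniformly at random."""
    return "".join(
        s if s in _BASES else rng.choice(_BITS_TO_BASES[IUPAC_BITS[s]])
        for s in consensus
    )


@dataclass
class SimConfig:
    """Generator parameters (the simulated study conditions).

    Defaults model a two-site survey with a moderate level of cross-site
    spacer sharing, mild leader-end turnover of shared arrays, and the
    array-length range (10-35 spacers) and per-type spacer-length bands
    seen in thermophile CRISPR arrays.
    """

    sites: tuple[str, ...] = ("siteA", "siteB")
    samples_per_site: int = 2
    spacers_per_site: int = 220
    sharing: float = 0.3
    array_length_range: tuple[int, int] = (10, 35)
    types: tuple[str, ...] = ("I-E", "I-B", "IIIAB")
    leader_additions: tuple[int, int] = (0, 2)
    distal_deletions: tuple[int, int] = (0, 1)
    abundance_sigma: float = 1.5
    sample_noise_sigma: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.sharing <= 1.0:
            raise ValueError("sharing fraction must lie in [0, 1]")
        if self.array_length_range[0] < 2:
            raise ValueError("arrays need at least two spacers")
        if len(self.sites) < 1 or self.samples_per_site < 1:
            raise ValueError("need at least one site and one sample per site")


@dataclass
class StrainArray:
    """One CRISPR array of one strain; spacers are leader-proximal first."""

    array_id: str
    type_label: str
    spacers: tuple[str, ...]
    shared: bool


@dataclass
class SiteStrain:
    strain_id: str
    site_id: str
    arrays: list[StrainArray]
    abundance: float


@dataclass
class PlantedProtospacer:
    spacer: str
    type_label: str
    origin_site: str
    phage_id: str
    start: int
    end: int
    strand: str
    pam: str
    mutations: int = 0


@dataclass
class Phage:
    phage_id: str
    site_id: str
    sequence: str
    genes: list[tuple[int, int, str]] = field(default_factory=list)
    planted: list[PlantedProtospacer] = field(default_factory=list)


@dataclass
class ReadRecord:
    read_id: str
    sample_id: str
    strain_id: str
    array_id: str
    first_index: int
    n_spacers: int
    orientation: str
    chimeric: bool = False


@dataclass
class CommunityTruth:
    """Everything the generator planted, serialisable to JSON."""

    config: SimConfig
    strains: dict[str, list[SiteStrain]]          # site -> strains
    samples: dict[str, str]                       # sample_id -> site_id
    phages: list[Phage] = field(default_factory=list)
    reads: list[ReadRecord] = field(default_factory=list)

    def site_spacers(self, site: str, types: Sequence[str] | None = None) -> set[str]:
        out = set()
        for strain in self.strains[site]:
            for arr in strain.arrays:
                if types is None or arr.type_label in types:
                    out.update(arr.spacers)
        return out

    def all_spacers(self) -> dict[str, tuple[str, str]]:
        """spacer sequence -> (type_label, one site carrying it)."""
        out: dict[str, tuple[str, str]] = {}
        for site, strains in self.strains.items():
            for strain in strains:
                for arr in strain.arrays:
                    for sp in arr.spacers:
                        out.setdefault(sp, (arr.type_label, site))
        return out

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=None,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CommunityTruth":
        raw = json.loads(text)
        cfg = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["config"].items()
        })
        strains = {
            site: [
                SiteStrain(
                    s["strain_id"], s["site_id"],
                    [StrainArray(a["array_id"], a["type_label"],
                                 tuple(a["spacers"]), a["shared"])
                     for a in s["arrays"]],
                    s["abundance"],
                )
                for s in lst
            ]
            for site, lst in raw["strains"].items()
        }
        phages = [
            Phage(p["phage_id"], p["site_id"], p["sequence"],
                  [tuple(g) for g in p["genes"]],
                  [PlantedProtospacer(**pp) for pp in p["planted"]])
            for p in raw["phages"]
        ]
        reads = [ReadRecord(**r) for r in raw["reads"]]
        return cls(cfg, strains, raw["samples"], phages, reads)


def _looks_like_repeat_fragment(spacer: str, consensus: str, max_mm: int = 1) -> bool:
    """True when the spacer contains a window within ``max_mm`` IUPAC
    mismatches of a terminal 8-mer of the repeat consensus.  Such spacers
    are indistinguishable from repeat contamination and are rejected by
    the extractor, so the generator never plants them."""
    from .repeats import iupac_mismatches

    if len(spacer) < 8:
        return False
    for frag in (consensus[:8], consensus[-8:]):
        for i in range(len(spacer) - 7):
            if iupac_mismatches(frag, spacer[i : i + 8]) <= max_mm:
                return True
    return False


def _spacer_length(rng: np.random.Generator, cons: RepeatConsensus) -> int:
    lo, hi = cons.spacer_band
    mid = cons.expected_spacer_length
    return int(np.clip(round(rng.normal(mid, 2.0)), lo, hi))


def _partition_lengths(
    rng: np.random.Generator, total: int, lo: int, hi: int
) -> list[int]:
    """Array lengths in [lo, hi] summing exactly to ``total`` (the last
    one may be shortened, never below 2, or folded into its neighbour)."""
    out: list[int] = []
    left = total
    while left > 0:
        n = int(rng.integers(lo, hi + 1))
        if left - n < 0:
            n = left
        out.append(n)
        left -= n
    if len(out) > 1 and out[-1] < 2:
        out[-2] += out.pop()
    return out


def simulate_community(config: SimConfig) -> CommunityTruth:
    """Generate strains, arrays and abundances for every site.

    Cross-site sharing is controlled at the spacer level: shared arrays
    (present at every site, subject to per-site leader additions and
    distal deletions) are generated first, then per-site private arrays
    top each repertoire up so that the realised shared fraction matches
    ``config.sharing``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cons_by_type = {c.type_label: c for c in default_repeats()}
    for t in config.types:
        if t not in cons_by_type:
            raise ValueError(f"unknown CRISPR type in config: {t}")

    lo, hi = config.array_length_range
    n_shared_target = round(config.sharing * config.spacers_per_site)

    def new_spacer(tlab: str) -> str:
        cons = cons_by_type[tlab]
        while True:
            s = random_dna(rng, _spacer_length(rng, cons))
            if not _looks_like_repeat_fragment(s, cons.sequence):
                return s

    # shared core arrays, dealt to every site with per-site turnover
    shared_site_arrays: dict[str, list[StrainArray]] = {s: [] for s in config.sites}
    aid = 0
    if len(config.sites) >= 2 and n_shared_target > 0:
        for alen in _partition_lengths(rng, n_shared_target, lo, hi):
            tlab = config.types[aid % len(config.types)]
            core = tuple(new_spacer(tlab) for _ in range(alen))
            for site in config.sites:
                n_del = int(rng.integers(config.distal_deletions[0],
                                         config.distal_deletions[1] + 1))
                n_add = int(rng.integers(config.leader_additions[0],
                                         config.leader_additions[1] + 1))
                spacers = core[: len(core) - n_del] if n_del else core
                additions = tuple(new_spacer(tlab) for _ in range(n_add))
                shared_site_arrays[site].append(
                    StrainArray(f"shared{aid:03d}@{site}", tlab,
                                additions + spacers, shared=True)
                )
            aid += 1

    # realised shared spacers (present at >= 2 sites after turnover)
    site_sets = {
        s: set().union(*(a.spacers for a in arrs)) if (arrs := shared_site_arrays[s]) else set()
        for s in config.sites
    }
    strains: dict[str, list[SiteStrain]] = {}
    for site in config.sites:
        others = set().union(*(site_sets[o] for o in config.sites if o != site)) \
            if len(config.sites) > 1 else set()
        n_shared_real = len(site_sets[site] & others)
        if config.sharing > 0 and len(config.sites) >= 2:
            target_total = round(n_shared_real / config.sharing) if n_shared_real else \
                config.spacers_per_site
        else:
            target_total = config.spacers_per_site
        n_private = max(0, target_total - len(site_sets[site]))
        arrays = list(shared_site_arrays[site])
        pid = 0
        left = n_private
        while left > 0:
            alen = int(rng.integers(lo, hi + 1))
            alen = min(alen, left) if left >= 2 else 2
            tlab = config.types[pid % len(config.types)]
            arrays.append(
                StrainArray(
                    f"priv-{site}-{pid:03d}", tlab,
                    tuple(new_spacer(tlab) for _ in range(alen)), shared=False,
                )
            )
            left -= alen
            pid += 1
        # one strain per array; log-normal strain abundances
        site_strains = []
        for k, arr in enumerate(arrays):
            ab = float(np.exp(rng.normal(0.0, config.abundance_sigma)))
            site_strains.append(
                SiteStrain(f"{site}-st{k:03d}", site, [arr], ab)
            )
        strains[site] = site_strains

    samples = {
        f"{site}-s{i + 1}": site
        for site in config.sites
        for i in range(config.samples_per_site)
    }
    return CommunityTruth(config=config, strains=strains, samples=samples)


_DEFAULT_PAMS = {"I-E": "AAG", "I-B": "GGTN", "I-C": "TTC", "I-U": "TTC"}


def simulate_phages(
    truth: CommunityTruth,
    n_phages: int = 2,
    protospacers_per_phage: int = 20,
    genome_length: int = 20000,
    pam_spec: dict[str, str] | None = None,
    locality: float = 0.9,
    mutations: tuple[int, int] = (0, 0),
    gene_length: int = 1000,
    strand_policy: dict[str, str] | None = None,
    edge_protospacer: bool = False,
    seed: int | None = None,
) -> list[Phage]:
    """Plant community spacers as protospacers in random phage genomes.

    Each phage is assigned a home site; a ``locality`` fraction of its
    protospacers come from that site's repertoire, the rest from other
    sites.  The 5' flank of every protospacer carries the type's PAM
    (degenerate symbols instantiated per planting).  Toy genes —
    alternating-strand blocks of ``gene_length`` — are recorded for
    strand-bias analyses.  ``strand_policy`` maps a type to ``template``
    (protospacer placed so the crRNA pairs with the transcript of the
    overlapping gene, the type III configuration) or ``random``; the
    default is template for IIIAB, random otherwise.
    """
    rng = np.random.default_rng(truth.config.seed + 104729 if seed is None else seed)
    pams = dict(_DEFAULT_PAMS)
    if pam_spec:
        pams.update(pam_spec)
    policy = {"IIIAB": "template"}
    if strand_policy:
        policy.update(strand_policy)

    by_site_type: dict[tuple[str, str], list[str]] = {}
    for site in truth.strains:
        for t in truth.config.types:
            by_site_type[(site, t)] = sorted(truth.site_spacers(site, [t]))

    sites = list(truth.strains)
    phages: list[Phage] = []
    for p in range(n_phages):
        home = sites[p % len(sites)]
        genome = list(random_dna(rng, genome_length))
        genes = [
            (s, min(s + gene_length, genome_length), "+" if (s // gene_length) % 2 == 0 else "-")
            for s in range(0, genome_length, gene_length)
        ]
        phage = Phage(f"phage{p:02d}", home, "", genes=genes)
        occupied: list[tuple[int, int]] = []

        def place(spacer: str, tlab: str, origin: str, at_edge: bool = False) -> None:
            n_mut = int(rng.integers(mutations[0], mutations[1] + 1))
            proto = list(spacer)
            for i in sorted(rng.choice(len(proto), size=n_mut, replace=False)) if n_mut else []:
                proto[i] = rng.choice([b for b in _BASES if b != proto[i]])
            proto_s = "".join(proto)
            pam = "".join(
                instantiate_repeat(rng, pams.get(tlab, ""))
            )
            for _try in range(200):
                if at_edge:
                    start = 0
                else:
                    start = int(rng.integers(len(pam) + 8,
                                             genome_length - len(spacer) - 8))
                end = start + len(spacer)
                if any(s_ < end + 12 and start < e_ + 12 for s_, e_ in occupied):
                    continue
                containing = [
                    gs for g0, g1, gs in genes if g0 <= start and end <= g1
                ]
                if not containing:
                    continue  # straddles a gene boundary; pick another spot
                gene_strand = containing[0]
                mode = policy.get(tlab, "random")
                if mode == "template":
                    strand = "-" if gene_strand == "+" else "+"
                elif mode == "coding":
                    strand = gene_strand
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    genome[start:end] = list(proto_s)
                    if pam and start >= len(pam):
                        genome[start - len(pam) : start] = list(pam)
                else:
                    genome[start:end] = list(revcomp(proto_s))
                    if pam and end + len(pam) <= genome_length:
                        genome[end : end + len(pam)] = list(revcomp(pam))
                occupied.append((start - len(pam), end + len(pam)))
                phage.planted.append(
                    PlantedProtospacer(spacer, tlab, origin, phage.phage_id,
                                       start, end, strand, pam, n_mut)
                )
                return
            raise ValueError("genome too short for requested protospacer count")

        for k in range(protospacers_per_phage):
            local = rng.random() < locality or len(sites) == 1
            origin = home if local else sites[(sites.index(home) + 1) % len(sites)]
            tlab = truth.config.types[k % len(truth.config.types)]
            pool = by_site_type[(origin, tlab)]
            if not pool:
                continue
            spacer = pool[int(rng.integers(len(pool)))]
            place(spacer, tlab, origin, at_edge=(edge_protospacer and k == 0 and p == 0))
        phage.sequence = "".join(genome)
        phages.append(phage)
    truth.phages = phages
    return phages


def simulate_reads(
    truth: CommunityTruth,
    reads_per_sample: int = 2000,
    unit_weights: tuple[float, ...] = (0.3, 0.35, 0.25, 0.1),
    error_rate: float = 0.005,
    phred: int = 33,
    chimera_fraction: float = 0.0,
    seed: int | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Amplicon reads spanning 1-4 repeat-spacer units, per sample.

    A read is repeat + spacer + repeat + ... + repeat (n units need
    n + 1 repeat copies), sampled from a strain chosen by abundance,
    with a random window inside one of its arrays, random orientation,
    uniform per-base substitution errors, and a flat Phred quality.
    Returns ``sample_id -> [(read_id, sequence, quality), ...]`` and
    appends per-read provenance to ``truth.reads``.

    ``chimera_fraction`` of reads join windows of two arrays of
    different types at one junction, exercising the chimera filter.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error rate must lie in [0, 0.05]")
    rng = np.random.default_rng(
        truth.config.seed + 15485863 if seed is None else seed
    )
    cons_by_type = {c.type_label: c for c in default_repeats()}
    # one concrete repeat instantiation per array (copies nearly identical)
    repeat_of: dict[str, str] = {}
    strain_arrays: dict[str, list[tuple[SiteStrain, StrainArray]]] = {}
    for site, site_strains in truth.strains.items():
        pairs = [(st, a) for st in site_strains for a in st.arrays]
        strain_arrays[site] = pairs
        for _st, a in pairs:
            repeat_of[a.array_id] = instantiate_repeat(
                rng, cons_by_type[a.type_label].sequence
            )

    weights = np.asarray(unit_weights, dtype=float)
    weights = weights / weights.sum()
    out: dict[str, list[tuple[str, str, str]]] = {}
    for sample_id in sorted(truth.samples):
        site = truth.samples[sample_id]
        pairs = strain_arrays[site]
        ab = np.array([st.abundance for st, _a in pairs], dtype=float)
        ab *= np.exp(rng.normal(0.0, truth.config.sample_noise_sigma, size=len(ab)))
        prob = ab / ab.sum()
        reads: list[tuple[str, str, str]] = []
        for r in range(reads_per_sample):
            rid = f"{sample_id}.r{r:06d}"
            k = int(rng.choice(len(pairs), p=prob))
            strain, arr = pairs[k]
            n_units = int(rng.choice(len(weights), p=weights)) + 1
            n_units = min(n_units, len(arr.spacers))
            first = int(rng.integers(0, len(arr.spacers) - n_units + 1))
            window = arr.spacers[first : first + n_units]
            rep = repeat_of[arr.array_id]
            chimeric = rng.random() < chimera_fraction
            if chimeric:
                other = [
                    (st2, a2) for st2, a2 in pairs if a2.type_label != arr.type_label
                ]
                if other:
                    st2, a2 = other[int(rng.integers(len(other)))]
                    j = int(rng.integers(0, len(a2.spacers)))
                    seq = (rep + window[0] + rep
                           + a2.spacers[j] + repeat_of[a2.array_id])
                    n_units = 1
                else:
                    chimeric = False
            if not chimeric:
                parts = [rep]
                for sp in window:
                    parts.append(sp)
                    parts.append(rep)
                seq = "".join(parts)
            orient = "+" if rng.random() < 0.5 else "-"
            if orient == "-":
                seq = revcomp(seq)
            if error_rate > 0:
                arrseq = np.frombuffer(seq.encode(), dtype="S1").copy()
                errs = np.flatnonzero(rng.random(len(seq)) < error_rate)
                for i in errs:
                    cur = arrseq[i].decode()
                    arrseq[i] = rng.choice([b for b in _BASES if b != cur]).encode()
                seq = arrseq.tobytes().decode()
            qual = chr(phred + 33) * len(seq)
            reads.append((rid, seq, qual))
            truth.reads.append(
                ReadRecord(rid, sample_id, strain.strain_id, arr.array_id,
                           first, n_units, orient, chimeric)
            )
        out[sample_id] = reads
    return out


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_phage_fasta(phages: Sequence[Phage], path) -> None:
    with open(path, "w") as fh:
        for p in phages:
            fh.write(f">{p.phage_id} site={p.site_id}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


def write_phage_gff(phages: Sequence[Phage], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in phages:
            for k, (s, e, strand) in enumerate(p.genes):
                fh.write(
                    "\t".join([p.phage_id, "sim", "gene", str(s + 1), str(e),
                               ".", strand, ".", f"ID={p.phage_id}.g{k:03d}"])
                    + "\n"
                )


def simulate_host_genome(
    arrays: Sequence[StrainArray],
    seed: int = 0,
    spacer_gap: int = 2000,
    flank: int = 3000,
) -> str:
    """A synthetic host contig embedding the given arrays (for array
    mining tests): random background with each array written as
    repeat/spacer alternation on the plus strand."""
    rng = np.random.default_rng(seed)
    cons_by_type = {c.type_label: c for c in default_repeats()}
    parts = [random_dna(rng, flank)]
    for arr in arrays:
        rep = instantiate_repeat(rng, cons_by_type[arr.type_label].sequence)
        body = [rep]
        for sp in arr.spacers:
            body.append(sp)
            body.append(rep)
        parts.append("".join(body))
        parts.append(random_dna(rng, spacer_gap))
    parts.append(random_dna(rng, flank - spacer_gap if flank > spacer_gap else flank))
    return "".join(parts)
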