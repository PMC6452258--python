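"""End-to-end orchestration: simulate -> extract -> cluster -> stats ->
share -> assemble -> map, with every stage handoff on disk as documented
TSV/FASTA/JSON so runs are auditable and resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assembly, cluster as clus, diversity, extract, protomap
from . import simulate as sim_mod
from .repeats import default_repeats, load_repeat_table

log = logging.getLogger("spacerscope")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    outdir: str = "spacerscope_run"
    seed: int = 0
    repeat_table: str | None = None  # None -> packaged default
    max_mismatch: int = 3
    min_qual: int = 20
    identity: float = 0.85
    min_size: int = 11
    min_support: int = 2
    word_size: int = 8
    min_hit_identity: float = 0.85
    beta_metrics: tuple[str, ...] = ("braycurtis", "jaccard")
    simulate: bool = True
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    reads_per_sample: int = 2000
    error_rate: float = 0.005
    n_phages: int = 2
    protospacers_per_phage: int = 20

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of key results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    (out / "config.json").write_text(config.to_json())
    consensi = (
        load_repeat_table(config.repeat_table)
        if config.repeat_table
        else default_repeats()
    )
    summary: dict = {"config_hash": h}

    # --- simulate -------------------------------------------------------
    if not config.simulate:
        raise NotImplementedError(
            "run_all currently drives the simulated workflow; run the "
            "stage commands individually for externally supplied reads"
        )
    config.sim.seed = config.seed
    truth = sim_mod.simulate_community(config.sim)
    phages = sim_mod.simulate_phages(
        truth,
        n_phages=config.n_phages,
        protospacers_per_phage=config.protospacers_per_phage,
    )
    reads = sim_mod.simulate_reads(
        truth, reads_per_sample=config.reads_per_sample, error_rate=config.error_rate
    )
    (out / "truth.json").write_text(truth.to_json())
    sim_mod.write_phage_fasta(phages, out / "phages.fasta")
    sim_mod.write_phage_gff(phages, out / "phages.gff3")
    for sample_id, recs in reads.items():
        sim_mod.write_fastq(recs, out / f"{sample_id}.fastq")
    log.info("simulate: %d samples, %d phages", len(reads), len(phages))

    # --- extract --------------------------------------------------------
    all_obs: list[extract.SpacerObservation] = []
    for sample_id, recs in sorted(reads.items()):
        stats = extract.ExtractionStats()
        site = truth.samples[sample_id]
        for rid, seq, qual in recs:
            all_obs.extend(
                extract.extract_from_read(
                    seq, [ord(c) - 33 for c in qual], consensi,
                    max_mismatch=config.max_mismatch, min_qual=config.min_qual,
                    sample_id=sample_id, site_id=site, source_id=rid, stats=stats,
                )
            )
        log.info(
            "extract %s: %d spacers from %d reads (%d chimera-candidates, "
            "%d out-of-band gaps)",
            sample_id, stats.n_spacers, stats.n_reads,
            len(stats.chimeric_reads), stats.out_of_band_gaps,
        )
    obs_df = extract.observations_to_frame(all_obs)
    _write_tsv(obs_df, out / "observations.tsv", h)
    summary["n_observations"] = len(all_obs)

    # --- cluster --------------------------------------------------------
    clusters = clus.cluster_all(all_obs, threshold=config.identity)
    retained = clus.filter_clusters(clusters, min_size=config.min_size)
    cl_rows = [
        {
            "cluster_id": c.cluster_id, "type_label": c.type_label,
            "sample_id": c.sample_id, "centre": c.centre_sequence,
            "size": c.size, "n_unique": c.n_unique,
            "retained": c in retained,
        }
        for c in clusters
    ]
    _write_tsv(pd.DataFrame(cl_rows), out / "clusters.tsv", h)
    log.info("cluster: %d clusters, %d retained (size >= %d)",
             len(clusters), len(retained), config.min_size)
    summary["n_clusters"] = len(clusters)
    summary["n_retained_clusters"] = len(retained)

    # --- per-sample stats ----------------------------------------------
    sample_ids = sorted(truth.samples)
    vectors = []
    for sample_id in sample_ids:
        counts = {
            c.cluster_id: c.size for c in clusters if c.sample_id == sample_id
        }
        if counts:
            vectors.append(diversity.AbundanceVector(sample_id, counts))
    stats_df = diversity.sample_stats(vectors)
    _write_tsv(stats_df, out / "sample_stats.tsv", h)
    summary["sample_stats"] = stats_df.to_dict("records")

    # --- cross-sample matching / sharing -------------------------------
    groups_by_sample = {
        s: [
            (c.cluster_id, c.centre_sequence, c.type_label)
            for c in retained
            if c.sample_id == s
        ]
        for s in sample_ids
    }
    mr_samples = clus.match_across(groups_by_sample)
    sites = sorted(set(truth.samples.values()))
    groups_by_site = {
        site: [
            rec
            for s in sample_ids
            if truth.samples[s] == site
            for rec in groups_by_sample[s]
        ]
        for site in sites
    }
    mr_sites = clus.match_across(groups_by_site)
    share_rows = [
        {"n_sites": k, "n_spacers": mr_sites.n_shared(k)}
        for k in sorted(mr_sites.shared_by)
    ]
    _write_tsv(pd.DataFrame(share_rows), out / "sharing_summary.tsv", h)
    summary["unique_spacers_global"] = mr_sites.n_components
    summary["unique_spacers_per_sample_sum"] = sum(
        len(v) for v in groups_by_sample.values()
    )
    summary["shared_by_sites"] = {k: mr_sites.n_shared(k) for k in sorted(mr_sites.shared_by)}

    # --- beta diversity / correlation ----------------------------------
    comp_vectors = []
    for sample_id in sample_ids:
        counts: dict[str, int] = {}
        for c in retained:
            if c.sample_id == sample_id:
                cid = f"comp{mr_samples.component_of[c.cluster_id]:05d}"
                counts[cid] = counts.get(cid, 0) + c.size
        if counts:
            comp_vectors.append(diversity.AbundanceVector(sample_id, counts))
    if len(comp_vectors) >= 2:
        for metric in config.beta_metrics:
            dm, nwk = diversity.beta_matrix(comp_vectors, metric=metric)
            _write_tsv(dm, out / f"beta_{metric}.tsv", h, index=True)
            (out / f"upgma_{metric}.nwk").write_text(nwk + "\n")
        corr_rows = []
        for i in range(len(comp_vectors)):
            for j in range(i + 1, len(comp_vectors)):
                a, b = comp_vectors[i], comp_vectors[j]
                r = diversity.shared_abundance_correlation(a, b)
                corr_rows.append(
                    {"sample_a": a.sample_id, "sample_b": b.sample_id, **r}
                )
        _write_tsv(pd.DataFrame(corr_rows), out / "abundance_correlation.tsv", h)
        summary["abundance_correlation"] = corr_rows

    # --- array assembly -------------------------------------------------
    frag_rows = []
    cluster_of = {seq: c.cluster_id for c in retained for seq in c.members}
    for sample_id in sample_ids:
        sobs = [o for o in all_obs if o.sample_id == sample_id]
        for tlab in sorted({o.type_label for o in sobs}):
            tobs = [o for o in sobs if o.type_label == tlab]
            graph = assembly.build_adjacency(tobs, cluster_of, config.min_support)
            frags = assembly.assemble_fragments(
                graph, type_label=tlab, samples=frozenset([sample_id])
            )
            for f in frags:
                frag_rows.append(
                    {
                        "fragment_id": f"{sample_id}|{f.fragment_id}",
                        "sample_id": sample_id,
                        "type_label": tlab,
                        "n_spacers": len(f),
                        "spacers": ",".join(f.spacers),
                        "junction_support": ",".join(map(str, f.junction_support)),
                    }
                )
    _write_tsv(pd.DataFrame(frag_rows), out / "fragments.tsv", h)
    summary["n_fragments"] = len(frag_rows)
    log.info("assemble: %d fragments", len(frag_rows))

    # --- protospacer mapping / PAM / locality / strand bias -------------
    centre_seqs = {c.cluster_id: c.centre_sequence for c in retained}
    centre_types = {c.cluster_id: c.type_label for c in retained}
    site_of_cluster = {
        c.cluster_id: truth.samples[c.sample_id] for c in retained
    }
    targets = {p.phage_id: p.sequence for p in phages}
    hits = protomap.search_protospacers(
        centre_seqs, targets,
        word_size=config.word_size, min_identity=config.min_hit_identity,
        spacer_types=centre_types, spacer_sites=site_of_cluster,
    )
    hit_df = pd.DataFrame(
        [
            {
                "spacer_id": x.spacer_id, "type_label": x.type_label,
                "site_id": x.site_id, "target_id": x.target_id,
                "strand": x.strand, "start": x.start + 1, "end": x.end,
                "identity": round(x.identity, 4), "mismatches": x.mismatches,
                "up_flank": x.up_flank or "", "down_flank": x.down_flank or "",
            }
            for x in hits
        ]
    )
    _write_tsv(hit_df, out / "hits.tsv", h)
    summary["n_hits"] = len(hits)

    pam_consensus: dict[str, str] = {}
    pam_lines = []
    for tlab in sorted({x.type_label for x in hits}):
        thits = [x for x in hits if x.type_label == tlab]
        if len(thits) < 5:
            continue
        model = protomap.build_pam(thits, type_label=tlab)
        pam_consensus[tlab] = model.up_consensus
        pam_lines.append(
            f"{tlab}\tup={model.up_consensus}\tdown={model.down_consensus}"
            f"\tn={model.n_hits}"
        )
        _write_tsv(model.up_counts, out / f"pam_up_{tlab}.tsv", h, index=True)
        _write_tsv(model.down_counts, out / f"pam_down_{tlab}.tsv", h, index=True)
    (out / "pam_consensus.txt").write_text(
        f"# config_hash={h}\n# upstream flank reported 5'->3' on the "
        "protospacer strand; PAM-proximal position is the rightmost\n"
        + "\n".join(pam_lines) + "\n"
    )
    summary["pam_consensus"] = pam_consensus

    loc_rows = []
    for p in phages:
        table, pval = protomap.locality_table(
            hits, site_of_cluster, p.site_id, p.phage_id
        )
        loc_rows.append(
            {
                "target": p.phage_id, "target_site": p.site_id,
                "local_hit": table[0][0], "local_nohit": table[0][1],
                "foreign_hit": table[1][0], "foreign_nohit": table[1][1],
                "fisher_p": pval,
            }
        )
    _write_tsv(pd.DataFrame(loc_rows), out / "locality.tsv", h)
    summary["locality"] = loc_rows

    genes = [
        protomap.Gene(p.phage_id, s, e, strand)
        for p in phages
        for (s, e, strand) in p.genes
    ]
    sb_rows = []
    for tlab in sorted({x.type_label for x in hits}):
        sb = protomap.strand_bias([x for x in hits if x.type_label == tlab], genes)
        sb_rows.append({"type_label": tlab, **sb})
    _write_tsv(pd.DataFrame(sb_rows), out / "strand_bias.tsv", h)
    summary["strand_bias"] = sb_rows

    site_tab = protomap.hits_by_site_table(hits)
    if not site_tab.empty:
        _write_tsv(site_tab, out / "hits_by_site.tsv", h, index=True)
    type_tab = protomap.hits_by_type_table(hits, pam_consensus)
    if not type_tab.empty:
        _write_tsv(type_tab, out / "hits_by_type.tsv", h, index=True)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
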