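# spacerscope

Profiling the natural diversity of CRISPR spacers in environmental
bacterial communities from repeat-anchored amplicon sequencing.

Thermophilic bacteria such as *Thermus* carry several CRISPR-Cas systems
whose arrays record past encounters with phages as short spacers between
near-identical direct repeats. Amplifying across those repeats with
degenerate primers and sequencing the amplicons yields millions of reads,
each spanning one to a few repeat–spacer units. `spacerscope` turns such
reads (or whole genomes) into comparable spacer repertoires and analyses
them:

- **Repeat matching** (`spacerscope.repeats`) — IUPAC-degenerate repeat
  consensi for six CRISPR types/subtypes (IIIAB, I-E, I-C, I-B, I-U, I-A)
  ship as a default table; approximate occurrences are located on both
  strands of arbitrary DNA with a configurable mismatch budget.
- **Spacer extraction** (`spacerscope.extract`) — a spacer is a sequence
  of expected length between two same-type repeat matches; the same
  machinery mines complete CRISPR arrays from genome FASTA.
- **Clustering** (`spacerscope.cluster`) — UCLUST-style greedy centroid
  clustering at 85% full-length identity with free end gaps, per sample
  and type; cluster centres (the most abundant member) are the repertoire
  unit. Across samples, centres differing by fewer than two mismatches
  count as the same spacer; unique spacers are connected components of
  that match graph.
- **Diversity** (`spacerscope.diversity`) — Shannon entropy (nats),
  bias-corrected Chao1 richness, Good's coverage `1 − n1/N`, Bray–Curtis /
  Jaccard β-diversity with UPGMA dendrograms, abundance correlations of
  shared spacers, and Fisher's exact tests.
- **Array assembly** (`spacerscope.assembly`) — spacer pairs and triplets
  observed within single reads build a support-weighted adjacency graph;
  maximal unambiguous chains (triplet-phased through branches) reconstruct
  array fragments, and fragment comparison classifies shared arrays as
  identical, end-trimmed or partially renewed across samples.
- **Protospacer mapping** (`spacerscope.protomap`) — ungapped
  seed-and-extend search (8-mer seeds, identity strictly > 0.85 over the
  whole spacer, no indels) against phage genomes; 8-nt flanks feed PAM
  count matrices and consensus calls; locality (local vs foreign spacer
  origin) and transcribed-strand bias are tested with exact statistics.
- **Synthetic communities** (`spacerscope.simulate`) — a ground-truthed
  generator of multi-site communities with log-normal strain abundances,
  partially shared arrays with leader-proximal turnover, phages carrying
  planted protospacers with type-specific PAMs, and error-bearing amplicon
  reads, so every stage is testable without any external download.

## Worked example

```python
from spacerscope.pipeline import RunConfig, run_all
from spacerscope.simulate import SimConfig

cfg = RunConfig(
    outdir="demo_run", seed=1, reads_per_sample=2500,
    sim=SimConfig(spacers_per_site=200, sharing=0.4,
                  types=("I-E", "I-B", "IIIAB")),
)
summary = run_all(cfg)
print(summary["n_observations"], summary["n_retained_clusters"],
      summary["unique_spacers_global"], summary["shared_by_sites"])
```

prints

```
20987 451 206 {1: 162, 2: 44}
```

i.e. 20 987 spacer observations were extracted from 10 000 reads of the
two-site community, 451 clusters survived the more-than-10-reads filter,
and matching their centres across sites left 206 unique spacers of which
44 were found at both sites. The run directory contains the per-sample
statistics table (`sample_stats.tsv`: N, clusters, Shannon, Chao1, Good's
coverage — Shannon 4.5–4.6 nats and coverage ≥ 99.7% for these deep
samples), the β-diversity matrices and UPGMA trees, reconstructed
array fragments with per-junction read support (`fragments.tsv`),
protospacer hits against the simulated phages (`hits.tsv`), PAM count
matrices and consensus calls (`pam_consensus.txt`: `up=NNNNNAAG` for I-E and
`up=NNNNGGTN` for I-B in this run), and locality/strand-bias test tables. Every table is stamped with a
hash of the run configuration.

The same stages are available from the shell:

```bash
spacerscope simulate --outdir sim --seed 1
spacerscope extract --reads sim/siteA-s1.fastq --sample siteA-s1 --out obs.tsv
spacerscope cluster --obs obs.tsv --out clusters.tsv
spacerscope stats --clusters clusters.tsv --out stats.tsv
spacerscope assemble --obs obs.tsv --clusters clusters.tsv --out frags.tsv
spacerscope map --spacers centres.fasta --targets sim/phages.fasta --out hits.tsv
spacerscope run-all --seed 1 --outdir demo_run
```

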