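# pupminer

Mining polyphenol utilization proteins (PUPs) and their gene clusters in
microbial genomes and metagenomes.

Dietary polyphenols reach the gut largely unabsorbed; gut bacteria carry
enzymes — hydrolases, reductases, transferases, lyases, isomerases — that
transform them into bioavailable metabolites. `pupminer` is a toolkit for
researchers who want to find candidate polyphenol-utilization enzymes in
annotated (meta)genomes and to study how they are organized and
distributed:

* **Family annotation.** A catalog of 26 PUP families in 6 enzyme classes
  (FR, OR, HR, NCR, IR, UC) is packaged with each family's *signature*
  Pfam domain or all-required multidomain combination. Proteins are
  assigned to a family when, after E-value/coverage filtering
  (E < 10⁻⁵, HMM coverage > 0.6 for homolog recruitment) and overlap
  resolution, every domain of the signature is present. The two
  domain-less UC families are assigned from iterative similarity-search
  evidence (E < 10⁻³) instead.
* **PUP gene clusters (PGCs).** On each contig, a PGC is a maximal run of
  genes with (i) ≥ 2 PUP genes, (ii) ≤ 3 non-PUP genes between adjacent
  PUP genes, and (iii) every intergenic gap < 1 kb. Each cluster's
  substrate is inferred by majority vote over the seed substrates of its
  PUP genes' families; ties return all tied substrates.
* **SSN subfamilies.** All-vs-all similarity edges below an E-value cutoff
  form a sequence similarity network; connected clusters of ≥ 10 sequences
  within a family are called subfamilies (optionally restricted to the
  2-core).
* **Profiling.** Genome-level abundance (percent of a genome's proteins
  that are PUPs or PGC genes), prevalence by phylum/continent,
  phylum-by-continent median "bubble" tables, and upper-tail
  hypergeometric enrichment of Pfam domains among PGC proteins
  (P(X ≥ k) for X ~ Hypergeom(N, K, n), with Benjamini–Hochberg
  adjustment).
* **Metagenome profiling.** Percent of reads whose best translated-search
  hit passes an E-value cutoff; RPKM per target/family; Welch two-sided
  t-tests between sample groups with */**/*** significance labels.
* **Synthetic data.** Seeded generators produce every input format the
  pipeline reads (GFF3, protein FASTA, HMMER-style domain tables,
  similarity edge lists, count tables) with ground-truth manifests, so the
  whole pipeline is testable without external databases.

## Worked example

Generate a synthetic genome with three planted PGCs and three
rule-violating decoys, annotate its proteins, and detect clusters:

```sh
$ pupminer simulate --seed 7 --out-dir fixture
stage=simulate seed=7 out_dir=fixture planted=3 decoys=3

$ pupminer annotate --domtbl fixture/domain_hits.domtbl --out annotations.tsv
stage=annotate hits_in=50 hits_kept=18 annotations=15 out=annotations.tsv

$ pupminer find-pgcs --gff fixture/genome.gff3 --annotations annotations.tsv --out pgcs.tsv
stage=find-pgcs contigs=4 pgcs=3 max_between=3 max_gap_bp=1000 out=pgcs.tsv
```

Of 50 raw domain hits, 18 survive the homolog filters (the rest are decoy
hits failing the E-value or coverage rule), yielding 15 annotated PUP
genes. Exactly the 3 planted clusters are detected — the lone-PUP,
4-intervening-gene, and >1 kb-gap decoys are all rejected. The output
table lists each cluster's span, member genes with family assignments,
and voted substrates:

```
pgc_id         contig   start  end    n_pup  n_other  substrates
contig2_pgc1   contig2  59219  63144  3      1        substrate_hr2;substrate_hr4;substrate_or7
```

Here three PUP genes (families HR2, OR7, HR4) each vote for a different
substrate group, so the tie returns all three. (The packaged catalog
carries synthetic per-family placeholder substrate labels; supply your own
catalog TSV to vote with real substrate names.)

Library use mirrors the CLI:

```python
from pupminer import load_catalog, detect_pgcs, infer_substrates

catalog = load_catalog()          # packaged 26-family catalog
pgcs = detect_pgcs(genes_by_contig)
for pgc in pgcs:
    pgc.substrates = infer_substrates(pgc, catalog)
```

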