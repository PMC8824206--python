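# Methods

## Family catalog and signature domains

The unit of classification is the *PUP family*: a set of proteins anchored
by experimentally characterized seed enzymes and recognized by a signature
Pfam domain or an all-required multidomain combination. Families group
into six enzyme classes by the first EC digit of their seeds: functional
group transfer (FR), oxidation/reduction (OR), hydrolysis (HR),
nonhydrolytic cleavage (NCR), isomerization (IR), and unclassified (UC,
seeds without any Pfam domain). The packaged catalog
(`pupminer/data/pup_families.tsv`) holds 26 families — 4 FR, 9 OR, 8 HR,
1 NCR, 2 IR, 2 UC — summing to 60 seeds, with per-family homolog counts
from Swiss-Prot (Σ = 5,788), TrEMBL (Σ = 50,906) and the unified human
gastrointestinal protein catalog, UHGP (Σ = 51,157).

Signature derivation (`derive_signature`) applies, after restricting every
member architecture to an enzymatic-domain allowlist: a single shared
single-domain architecture gives that domain; one identical multidomain
architecture across members gives the whole combination; members that
differ but share exactly one domain give that domain; members sharing
several domains give the shared subset. Which Pfam domains count as
"enzymatic" is inherently a curation judgment, so it is shipped as an
editable allowlist file rather than hard-coded; the packaged list contains
exactly the domains appearing in catalog signatures.

The per-seed substrate table is not public, so the packaged catalog
carries synthetic per-family placeholder substrate labels
(`substrate_<family>`). This keeps substrate inference fully exercised
without inventing real chemical assignments; users supply their own
catalog TSV for real substrate vocabularies. UC families carry no
signature; their members are recruited by iterative similarity search, and
catalog validation treats an empty signature as legal exactly for UC.

## Domain-hit filtering and family assignment

Hits come from HMMER per-domain tables in the `hmmscan` orientation
(target = HMM, query = protein); the per-domain *independent* E-value is
used. Coverage is defined as HMM-span/HMM-length — we fix the "alignment
length" of the coverage ratio to the span on HMM coordinates, which is
insensitive to protein-side insertions. Thresholds are strict
inequalities: E < 10⁻⁵ with coverage > 0.3 when characterizing seed
proteins and > 0.6 when recruiting homologs (the stricter coverage guards
against fragment matches in large databases).

Overlapping hits on one protein (the source data is silent on these) are
resolved greedily: hits are ranked by E-value, then longer alignment, then
lexicographic domain name, and a hit is dropped when it overlaps an
accepted hit by more than 50% of the shorter alignment. A protein is
assigned family *F* iff every domain of *F*'s signature is present among
its surviving hits, in any order and at any spacing — presence-only, since
no ordering or exclusivity rule is defined for multidomain signatures. A
protein satisfying several signatures keeps all assignments and is flagged
`multi_family` with a logged warning. Search execution itself (hmmscan,
iterative PSI-BLAST-style searches) is out of process: the package
consumes precomputed tables, and UC evidence is supplied as final-round
similarity hits filtered at E < 10⁻³.

## PGC detection

Gene models come from GFF3 (via `gffutils`, feature type `CDS` by
default, configurable to `gene`), linked to annotations through the `ID`
attribute and sorted per contig by start, then end, then id. The
intergenic gap between 1-based inclusive genes is
`max(0, next.start − prev.end − 1)`; overlapping or adjacent genes have
gap 0.

A PGC is a maximal run of genes satisfying: (i) ≥ 2 PUP genes; (ii) at
most 3 non-PUP genes between adjacent PUP genes; (iii) every consecutive
intergenic gap inside the run < 1,000 bp. Design choices where the rules
leave freedom:

* the < 1 kb constraint applies to *every* consecutive pair in the run
  (PUP–other and other–other alike), reading "all the intergenic lengths"
  as universal;
* clusters are trimmed to start and end at PUP genes, so intervening
  genes are the only place non-PUPs appear;
* strand is ignored (operon structure is motivation, not a rule);
* any annotated feature of the chosen type counts as an "other gene".

Detection links consecutive PUP genes left to right when rules (ii) and
(iii) hold along the stretch between them. Because two overlapping
rule-satisfying runs always merge into a single rule-satisfying run, the
greedy chains coincide with exhaustive maximal-window enumeration; the
test suite checks this equivalence against a brute-force oracle on random
contigs whose gap distribution straddles the 1 kb boundary, and
monotonicity of recovered PUP genes in both parameters.

Substrate inference is a majority vote: each PUP gene votes once per
distinct substrate across its families (a gene annotated into two
families with the same substrate still votes once for it); the
highest-vote substrate wins and ties return every tied substrate. Genes
whose families carry no substrate labels are excluded with a warning.

## SSN subfamilies

Edges are read from 3-column or standard 12-column tabular search output,
self-hits dropped and unordered duplicates collapsed to the best E-value.
Thresholding keeps edges strictly below the cutoff while retaining all
proteins as nodes. "Well-connected" clusters were identified manually in
the original curation; as a reproducible proxy the default is a connected
component of ≥ 10 nodes, with `kcore` mode offering the stricter 2-core
variant. Subfamilies are numbered per family by decreasing size with ties
broken by smallest member id, making numbering independent of input
order. Per-family cutoffs vary widely in practice (10⁻⁵ down to 10⁻¹⁸⁰)
and are user input; the default is 10⁻⁵.

## Abundance, prevalence, enrichment

Genome abundance is 100 × (PUP genes or PGC genes)/proteins; prevalence
of a phylum or continent group is 100 × (genomes with ≥ 1 indicated
gene)/(genomes in group). The bubble table reports the median per-genome
percentage per phylum × continent cell and ranks continents within each
phylum (1 = largest median, competition ranking on ties); genomes with
unknown continent are excluded from the bubble table but form an
`unknown` group in prevalence tables. Lineages are GTDB-style strings;
the phylum is the second rank.

Enrichment of a Pfam domain among PGC proteins uses the upper-tail
hypergeometric probability P(X ≥ k) with foreground size n, background
size N and K background carriers, counting per protein (a protein with
several copies of a domain counts once, matching per-protein occurrence
reporting). Raw p-values are the primary output, ordered by foreground
occurrence; Benjamini–Hochberg adjusted values are reported alongside.
The implementation is checked against exhaustive integer-binomial
enumeration for all N ≤ 60.

## Metagenome profiling

Percent-mapped keeps one best (lowest-E) hit per read and counts reads
passing E < 10⁻⁵ (the cutoff is configurable, as the original read-search
threshold is unstated). RPKM is reads/((length/10³)(mapped/10⁶)); the
module exposes per-target, per-family and per-sample aggregations since
the appropriate unit depends on the question. Group contrasts use Welch's
two-sided t-test by default (robust to unequal variances; pooled-variance
option available) with labels \*\*\* p < 0.001, \*\* p < 0.01, \* p < 0.05,
else n.s.

## Synthetic data

The genome generator plants PGCs that satisfy all three rules with margin
(intra-cluster gaps 50–900 bp, 0–3 intervening genes, 2–4 PUP genes per
cluster) and separates structures by background gaps of 1,100–4,000 bp so
nothing clusters by accident. Decoys each violate exactly one rule: a
lone PUP gene, a PUP pair split by four intervening genes, and a PUP pair
with a 1,000–1,500 bp gap. Non-PUP filler genes occasionally carry
domain hits that fail the E-value or coverage filter, exercising the
filtering stage. Protein sequences are uniform random 20-letter strings
and domain tables are written directly — no claim of sequence realism is
made, so passing tests demonstrate the correctness of filtering, rule
logic and bookkeeping, not detection performance on real divergent
homologs, fragmented assemblies or erroneous gene calls.

The SSN generator plants blocks with within-block E-values at most
`within_e` (a path backbone plus ~80%-dense extra edges guarantees
connectivity) and single between-block edges at least `between_e`, so any
cutoff strictly between the two levels recovers the blocks exactly. The
count generator draws negative-binomial reads per target
(`NB(mean, size = dispersion)`); with dispersion 50 and means 100 vs 142
the group difference is ≈ 2 pooled standard deviations, the effect size
used for the power calibration (200 seeded replicates, 15 samples per
group). All generators are deterministic functions of one integer seed,
recorded in each artifact's header line.

## Problem sizes and numerics

Default verification sizes — 1,000 random contigs of ≤ 50 genes for the
detector/oracle equivalence, 100 seeded genomes for planted
precision/recall, exhaustive hypergeometric enumeration to N = 60, and
200 Monte-Carlo replicates for power/type-I — were chosen so the whole
verification suite completes in well under a minute while keeping
binomial sampling error small (e.g., ±3 percentage points around a 5%
type-I rate at 200 replicates). Floating-point comparisons against exact
integer enumeration use a 10⁻⁹ relative tolerance; the survival function
is clipped to 1 to guard round-up at k = 0.

## Known limitations

* Family assignment is presence-based; it does not require the signature
  hit to be the protein's best hit, and proteins matching several
  signatures keep all families.
* PGC detection depends on assembly contiguity; clusters split across
  contigs are invisible, and no cross-contig stitching is attempted.
* Subfamily calling approximates manual curation with components/2-cores;
  per-family cutoffs must be supplied by the user.
* The packaged substrate vocabulary is placeholder-only (see above), so
  substrate outputs from the packaged catalog identify family groups, not
  chemicals.
* Read mapping, alignment, HMM search and MSA/phylogeny construction are
  external; the package consumes their tabular outputs and exports FASTA
  for downstream tools.
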