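"""Seeded generators for every input the pipeline consumes.

Each generator writes the same plain-text formats the pipeline reads (GFF3,
protein FASTA, HMMER-style per-domain tables, TSVs) together with a
ground-truth manifest, so detection and inference can be scored against
planted structure without external databases.  All outputs are
deterministic functions of the configured RNG seed.

The genome generator plants PUP gene clusters that satisfy the three
cluster rules with margin, plus optional decoys that each violate exactly
one rule: a lone PUP gene (rule i), a PUP pair separated by four non-PUP
genes (rule ii), and a PUP pair separated by an intergenic gap over 1 kb
(rule iii).  Protein sequences are random 20-letter strings; no sequence
realism is claimed, and domain-hit tables are written directly rather than
produced by live HMM search.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .catalog import SeedCatalog, load_catalog

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DECOY_TYPES = ("rule_i", "rule_ii", "rule_iii")


@dataclass
class SimulationConfig:
    """Layout parameters for one synthetic annotated genome.

    Gap ranges are intergenic base counts: intra-cluster gaps stay below
    the 1 kb rule with margin, background gaps stay at or above it so that
    planted structures cannot merge by accident.
    """

    rng_seed: int = 0
    n_contigs: int = 4
    genes_per_contig: tuple[int, int] = (20, 35)
    n_planted_pgcs: int = 3
    decoy_spec: dict[str, int] = field(
        default_factory=lambda: {"rule_i": 1, "rule_ii": 1, "rule_iii": 1}
    )
    family_pool: tuple[str, ...] = ()
    intra_gap_bp: tuple[int, int] = (50, 900)
    background_gap_bp: tuple[int, int] = (1100, 4000)
    gene_length_bp: tuple[int, int] = (300, 2400)

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.intra_gap_bp[1] >= 1000:
            raise ValueError("intra-cluster gaps must stay below 1000 bp")
        if self.background_gap_bp[0] < 1000:
            raise ValueError("background gaps must be >= 1000 bp")
        unknown = set(self.decoy_spec) - set(DECOY_TYPES)
        if unknown:
            raise ValueError(f"unknown decoy types: {sorted(unknown)}")


@dataclass
class SimulatedGenome:
    """Paths to the generated fixture files plus the truth manifest."""

    gff_path: Path
    fasta_path: Path
    domtbl_path: Path
    manifest_path: Path
    manifest: dict


@dataclass
class _GeneSpec:
    gene_id: str
    length: int
    gap_after: int  # intergenic bp to the next gene
    families: tuple[str, ...] = ()
    bad_hit: str | None = None  # "evalue" | "coverage" decoy hit on a non-PUP gene
    role: str = "filler"  # filler | planted | decoy


def _segment_planted(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    families: Sequence[str],
    next_id,
) -> list[_GeneSpec]:
    n_pup = int(rng.integers(2, 5))
    specs: list[_GeneSpec] = []
    for i in range(n_pup):
        specs.append(
            _GeneSpec(
                gene_id=next_id(),
                length=int(rng.integers(*cfg.gene_length_bp)),
                gap_after=int(rng.integers(cfg.intra_gap_bp[0], cfg.intra_gap_bp[1] + 1)),
                families=(str(rng.choice(families)),),
                role="planted",
            )
        )
        if i < n_pup - 1:
            for _ in range(int(rng.integers(0, 4))):  # <= 3 intervening genes
                specs.append(
                    _GeneSpec(
                        gene_id=next_id(),
                        length=int(rng.integers(*cfg.gene_length_bp)),
                        gap_after=int(
                            rng.integers(cfg.intra_gap_bp[0], cfg.intra_gap_bp[1] + 1)
                        ),
                        role="planted",
                    )
                )
    return specs


def _segment_decoy(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    decoy_type: str,
    families: Sequence[str],
    next_id,
) -> list[_GeneSpec]:
    def gene(families_=(), gap_lo=None, gap_hi=None):
        lo, hi = (
            (cfg.intra_gap_bp[0], cfg.intra_gap_bp[1])
            if gap_lo is None
            else (gap_lo, gap_hi)
        )
        return _GeneSpec(
            gene_id=next_id(),
            length=int(rng.integers(*cfg.gene_length_bp)),
            gap_after=int(rng.integers(lo, hi + 1)),
            families=families_,
            role="decoy",
        )

    fam = lambda: (str(rng.choice(families)),)
    if decoy_type == "rule_i":  # a lone PUP gene
        return [gene(fam())]
    if decoy_type == "rule_ii":  # four intervening genes between two PUPs
        return [gene(fam())] + [gene() for _ in range(4)] + [gene(fam())]
    # rule_iii: adjacent PUP pair with an intergenic gap of 1000..1500 bp
    first = gene(fam(), gap_lo=1000, gap_hi=1500)
    return [first, gene(fam())]


def _write_domtbl_row(fh, domain: str, hmm_len: int, protein: str, plen: int,
                      evalue: float, hmm_from: int, hmm_to: int,
                      ali_from: int, ali_to: int) -> None:
    fh.write(
        f"{domain} - {hmm_len} {protein} - {plen} "
        f"{evalue:.1e} 100.0 0.1 1 1 {evalue:.1e} {evalue:.1e} 99.0 0.1 "
        f"{hmm_from} {hmm_to} {ali_from} {ali_to} {ali_from} {ali_to} 0.95 -\n"
    )


def simulate_genome(
    config: SimulationConfig,
    out_dir: str | Path,
    catalog: SeedCatalog | None = None,
) -> SimulatedGenome:
    """Write a synthetic annotated genome with planted PGCs and decoys.

    Produces ``genome.gff3``, ``proteins.faa``, ``domain_hits.domtbl`` and
    ``truth.json`` under *out_dir*.  The manifest records each planted
    cluster's PUP genes, families, and the substrate call expected from the
    majority rule, plus the identity of every decoy.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    families = list(config.family_pool) or sorted(
        f for f, fam in catalog.families.items() if fam.signature_domains
    )
    for f in families:
        if f not in catalog.families or not catalog.families[f].signature_domains:
            raise ValueError(f"family {f} missing from catalog or lacks a signature")

    # distribute planted clusters and decoys round-robin over contigs
    jobs: list[tuple[int, str]] = []
    for i in range(config.n_planted_pgcs):
        jobs.append((i % config.n_contigs, "planted"))
    k = config.n_planted_pgcs
    for decoy_type in DECOY_TYPES:
        for _ in range(config.decoy_spec.get(decoy_type, 0)):
            jobs.append((k % config.n_contigs, decoy_type))
            k += 1

    counter = [0]

    manifest: dict = {
        "rng_seed": config.rng_seed,
        "planted_pgcs": [],
        "decoys": [],
        "pup_gene_families": {},
    }
    contig_specs: dict[str, list[_GeneSpec]] = {}
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"

        def next_id(contig=contig):
            counter[0] += 1
            return f"{contig}_g{counter[0]}"

        specs: list[_GeneSpec] = []
        n_filler = int(rng.integers(*config.genes_per_contig))
        contig_jobs = [job for tc, job in jobs if tc == ci]
        # filler genes split into runs around the planted segments
        cuts = sorted(rng.integers(0, n_filler + 1, size=len(contig_jobs)).tolist())
        filler_done = 0
        for cut, job in zip(cuts, contig_jobs):
            while filler_done < cut:
                specs.append(_filler(rng, config, next_id))
                filler_done += 1
            if specs:
                specs[-1].gap_after = _bg_gap(rng, config)
            if job == "planted":
                seg = _segment_planted(rng, config, families, next_id)
                pup_genes = [s for s in seg if s.families]
                expected = _majority_substrates(pup_genes, catalog)
                manifest["planted_pgcs"].append(
                    {
                        "contig": contig,
                        "gene_ids": [s.gene_id for s in seg],
                        "pup_gene_ids": [s.gene_id for s in pup_genes],
                        "families": [s.families[0] for s in pup_genes],
                        "expected_substrates": sorted(expected),
                    }
                )
            else:
                seg = _segment_decoy(rng, config, job, families, next_id)
                manifest["decoys"].append(
                    {
                        "contig": contig,
                        "type": job,
                        "gene_ids": [s.gene_id for s in seg],
                        "pup_gene_ids": [s.gene_id for s in seg if s.families],
                    }
                )
            specs.extend(seg)
            specs[-1].gap_after = _bg_gap(rng, config)
        while filler_done < n_filler:
            specs.append(_filler(rng, config, next_id))
            filler_done += 1
        if not specs:
            raise ValueError(f"contig {contig}: empty layout (widen genes_per_contig)")
        contig_specs[contig] = specs

    for specs in contig_specs.values():
        for s in specs:
            if s.families:
                manifest["pup_gene_families"][s.gene_id] = list(s.families)

    gff_path = out_dir / "genome.gff3"
    fasta_path = out_dir / "proteins.faa"
    domtbl_path = out_dir / "domain_hits.domtbl"
    manifest_path = out_dir / "truth.json"

    records: list[SeqRecord] = []
    with open(gff_path, "w", encoding="utf-8") as gff, open(
        domtbl_path, "w", encoding="utf-8"
    ) as dom:
        gff.write("##gff-version 3\n")
        gff.write(f"# pupminer synthetic genome; rng_seed={config.rng_seed}\n")
        dom.write(f"# pupminer synthetic domain hits; rng_seed={config.rng_seed}\n")
        dom.write("# target_name acc tlen query_name acc qlen E-value score bias "
                  "# of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from "
                  "ali_to env_from env_to acc description\n")
        for contig in sorted(contig_specs):
            cursor = int(rng.integers(1, 500))
            for s in contig_specs[contig]:
                start, end = cursor, cursor + s.length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                gff.write(
                    f"{contig}\tpupsim\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                    f"ID={s.gene_id}\n"
                )
                cursor = end + s.gap_after + 1
                plen = max(s.length // 3, 60)
                seq = "".join(rng.choice(AMINO_ACIDS, size=plen))
                records.append(SeqRecord(Seq(seq), id=s.gene_id, description=""))
                _write_hits(dom, rng, s, plen, catalog)
    SeqIO.write(records, str(fasta_path), "fasta")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return SimulatedGenome(
        gff_path=gff_path,
        fasta_path=fasta_path,
        domtbl_path=domtbl_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def _filler(rng: np.random.Generator, cfg: SimulationConfig, next_id) -> _GeneSpec:
    bad_hit = None
    r = rng.random()
    if r < 0.15:
        bad_hit = "evalue"
    elif r < 0.3:
        bad_hit = "coverage"
    return _GeneSpec(
        gene_id=next_id(),
        length=int(rng.integers(*cfg.gene_length_bp)),
        gap_after=_bg_gap(rng, cfg),
        bad_hit=bad_hit,
    )


def _bg_gap(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return int(rng.integers(cfg.background_gap_bp[0], cfg.background_gap_bp[1] + 1))


def _majority_substrates(
    pup_genes: Sequence[_GeneSpec], catalog: SeedCatalog
) -> set[str]:
    votes: Counter[str] = Counter()
    for s in pup_genes:
        subs: set[str] = set()
        for f in s.families:
            subs |= catalog.families[f].substrates
        votes.update(subs)
    if not votes:
        return set()
    top = max(votes.values())
    return {sub for sub, c in votes.items() if c == top}


def _write_hits(
    dom, rng: np.random.Generator, spec: _GeneSpec, plen: int, catalog: SeedCatalog
) -> None:
    if spec.families:
        signature = sorted(
            set().union(*(catalog.families[f].signature_domains for f in spec.families))
        )
        block = plen // len(signature)
        for i, domain in enumerate(signature):
            hmm_len = int(rng.integers(100, 400))
            covered = int(hmm_len * rng.uniform(0.7, 0.95))
            hmm_from = int(rng.integers(1, hmm_len - covered + 1))
            ali_from = i * block + 1
            ali_to = min((i + 1) * block, plen)
            evalue = 10.0 ** rng.uniform(-60, -10)
            _write_domtbl_row(
                dom, domain, hmm_len, spec.gene_id, plen, evalue,
                hmm_from, hmm_from + covered - 1, ali_from, ali_to,
            )
    elif spec.bad_hit is not None:
        hmm_len = 200
        if spec.bad_hit == "evalue":  # fails the E < 1e-5 filter
            evalue, hmm_from, hmm_to = 1e-3, 11, 190
        else:  # coverage 0.5: passes seed mode, fails homolog mode
            evalue, hmm_from, hmm_to = 1e-20, 1, 100
        ali_to = min(hmm_to - hmm_from + 1, plen)
        _write_domtbl_row(
            dom, "Alpha-amylase", hmm_len, spec.gene_id, plen, evalue,
            hmm_from, hmm_to, 1, ali_to,
        )


def simulate_ssn(
    block_sizes: Sequence[int],
    within_e: float = 1e-50,
    between_e: float = 1e-3,
    rng_seed: int = 0,
    within_density: float = 0.8,
) -> tuple[pd.DataFrame, list[set[str]]]:
    """Planted-partition similarity edges: dense blocks, weak inter-block ties.

    Within-block edges carry E-values at or below *within_e* (a ring
    guarantees connectivity); adjacent blocks are joined by single edges at
    or above *between_e*.  With a cutoff strictly between the two levels,
    thresholding recovers the blocks exactly.

    Returns the edge table (query, subject, evalue) and the planted blocks.
    """
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(rng_seed)
    rows: list[tuple[str, str, float]] = []
    blocks: list[set[str]] = []
    for bi, size in enumerate(block_sizes):
        nodes = [f"b{bi + 1}_n{j + 1}" for j in range(size)]
        blocks.append(set(nodes))
        for j in range(size - 1):  # connectivity backbone
            rows.append((nodes[j], nodes[j + 1], within_e * 10 ** rng.uniform(-2, 0)))
        for j in range(size):
            for k in range(j + 2, size):
                if rng.random() < within_density:
                    rows.append((nodes[j], nodes[k], within_e * 10 ** rng.uniform(-2, 0)))
    for bi in range(len(block_sizes) - 1):
        rows.append(
            (
                f"b{bi + 1}_n1",
                f"b{bi + 2}_n1",
                between_e * 10 ** rng.uniform(0, 2),
            )
        )
    return pd.DataFrame(rows, columns=["query", "subject", "evalue"]), blocks


def simulate_metagenome_counts(
    group_means: Mapping[str, float],
    n_samples: int = 15,
    dispersion: float = 50.0,
    rng_seed: int = 0,
    n_targets: int = 5,
    target_length_bp: int = 1500,
    total_reads: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial per-target read counts for two or more sample groups.

    Counts for every target in a sample are drawn NB(mean=group mean,
    size=*dispersion*); larger dispersion approaches Poisson.  Returns a
    sample sheet (sample_id, group, total_reads) and a long count table
    (sample_id, target_id, length_bp, count), both deterministic per seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 per group")
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(rng_seed)
    sheet_rows = []
    count_rows = []
    for group in sorted(group_means):
        mean = group_means[group]
        p = dispersion / (dispersion + mean)
        for si in range(n_samples):
            sample_id = f"{group}_s{si + 1}"
            sheet_rows.append(
                {"sample_id": sample_id, "group": group, "total_reads": total_reads}
            )
            counts = rng.negative_binomial(dispersion, p, size=n_targets)
            for ti, c in enumerate(counts):
                count_rows.append(
                    {
                        "sample_id": sample_id,
                        "target_id": f"pup_{ti + 1}",
                        "length_bp": target_length_bp,
                        "count": int(c),
                    }
                )
    return pd.DataFrame(sheet_rows), pd.DataFrame(count_rows)
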