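"""Detection of physically linked PUP gene clusters (PGCs) on contigs.

A PGC is a run of genes on one contig that satisfies three rules:

(i)   it contains at least two PUP homolog genes;
(ii)  no more than three non-PUP genes lie between two adjacent PUP genes;
(iii) every intergenic gap between consecutive genes in the run is < 1 kb.

Clusters are maximal, trimmed to start and end at PUP genes, and each PUP
gene belongs to at most one cluster.  Strand is ignored.  Each cluster's
substrate is inferred by majority vote over the seed substrates of its PUP
genes' families; ties return every tied substrate.
"""

from __future__ import annotations

import csv
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils

from .annotate import PupAnnotation
from .catalog import SeedCatalog

logger = logging.getLogger(__name__)

MAX_BETWEEN = 3
MAX_GAP_BP = 1000


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig (1-based inclusive coordinates)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."
    is_pup: bool = False
    family_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.is_pup != bool(self.family_ids):
            raise ValueError(
                f"gene {self.gene_id}: is_pup must hold iff family_ids is non-empty"
            )


@dataclass
class PGC:
    """A detected PUP gene cluster: an ordered run of genes on one contig."""

    pgc_id: str
    contig: str
    genes: tuple[GeneFeature, ...]
    substrates: set[str] = field(default_factory=set)

    @property
    def n_pup(self) -> int:
        return sum(g.is_pup for g in self.genes)

    @property
    def n_other(self) -> int:
        return len(self.genes) - self.n_pup

    @property
    def span(self) -> tuple[int, int]:
        return (self.genes[0].start, self.genes[-1].end)

    def validates_rules(
        self, max_between: int = MAX_BETWEEN, max_gap_bp: int = MAX_GAP_BP
    ) -> bool:
        """Re-check the three cluster rules independently of the detector."""
        if len({g.contig for g in self.genes}) != 1:
            return False
        if not (self.genes[0].is_pup and self.genes[-1].is_pup):
            return False
        if self.n_pup < 2:
            return False
        pup_pos = [i for i, g in enumerate(self.genes) if g.is_pup]
        if any(b - a - 1 > max_between for a, b in zip(pup_pos, pup_pos[1:])):
            return False
        return all(
            intergenic_gap(a, b) < max_gap_bp
            for a, b in zip(self.genes, self.genes[1:])
        )


def intergenic_gap(g1: GeneFeature, g2: GeneFeature) -> int:
    """Base pairs strictly between two genes; overlap or adjacency gives 0.

    Requires the genes on one contig with ``g1.start <= g2.start``.
    """
    if g1.contig != g2.contig:
        raise ValueError(f"genes on different contigs: {g1.contig} vs {g2.contig}")
    if g1.start > g2.start:
        raise ValueError("g1 must not start after g2")
    return max(0, g2.start - g1.end - 1)


def load_gene_features(
    gff_path: str | Path,
    annotations: Sequence[PupAnnotation],
    feature_type: str = "CDS",
) -> dict[str, list[GeneFeature]]:
    """Build per-contig sorted gene lists from GFF3 and PUP annotations.

    Features of *feature_type* are linked to annotation ``protein_id`` via
    their ``ID`` attribute.  Genes are sorted by start (ties by end, then
    gene id).  Features lacking an ``ID`` raise an error naming them.
    """
    families_by_protein: dict[str, set[str]] = {}
    for ann in annotations:
        families_by_protein.setdefault(ann.protein_id, set()).add(ann.family_id)

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    missing_ids: list[str] = []
    by_contig: dict[str, list[GeneFeature]] = {}
    for feat in db.features_of_type(feature_type):
        ids = feat.attributes.get("ID")
        if not ids:
            missing_ids.append(f"{feat.seqid}:{feat.start}-{feat.end}")
            continue
        gene_id = ids[0]
        fams = frozenset(families_by_protein.get(gene_id, ()))
        by_contig.setdefault(feat.seqid, []).append(
            GeneFeature(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                is_pup=bool(fams),
                family_ids=fams,
            )
        )
    if missing_ids:
        raise ValueError(
            f"{len(missing_ids)} {feature_type} features lack an ID attribute: "
            + ", ".join(missing_ids[:10])
        )
    for contig in by_contig:
        by_contig[contig].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_contig


def _check_sorted(genes: Sequence[GeneFeature]) -> None:
    for a, b in zip(genes, genes[1:]):
        if (a.start, a.end) > (b.start, b.end):
            raise ValueError(f"genes not sorted by start: {a.gene_id} before {b.gene_id}")


def detect_pgcs(
    genes: Mapping[str, Sequence[GeneFeature]] | Sequence[GeneFeature],
    max_between: int = MAX_BETWEEN,
    max_gap_bp: int = MAX_GAP_BP,
) -> list[PGC]:
    """Find all maximal PGCs in per-contig sorted gene lists.

    Greedy left-to-right linking: the next PUP gene joins the open cluster
    when at most *max_between* non-PUP genes separate it from the previous
    PUP gene and every consecutive intergenic gap along that stretch is
    below *max_gap_bp*.  Because any two overlapping rule-satisfying runs
    merge into one, the greedy maximal clusters coincide with exhaustive
    window enumeration.
    """
    if not isinstance(genes, Mapping):
        genes = {"": list(genes)}
    pgcs: list[PGC] = []
    for contig in sorted(genes):
        contig_genes = list(genes[contig])
        _check_sorted(contig_genes)
        pup_idx = [i for i, g in enumerate(contig_genes) if g.is_pup]
        chains: list[list[int]] = []
        for idx in pup_idx:
            if chains and _links(contig_genes, chains[-1][-1], idx, max_between, max_gap_bp):
                chains[-1].append(idx)
            else:
                chains.append([idx])
        counter = 0
        for chain in chains:
            if len(chain) < 2:
                continue
            counter += 1
            members = tuple(contig_genes[chain[0] : chain[-1] + 1])
            name = members[0].contig or "contig"
            pgcs.append(PGC(pgc_id=f"{name}_pgc{counter}", contig=members[0].contig, genes=members))
    return pgcs


def _links(
    genes: Sequence[GeneFeature],
    prev: int,
    nxt: int,
    max_between: int,
    max_gap_bp: int,
) -> bool:
    if nxt - prev - 1 > max_between:
        return False
    return all(
        intergenic_gap(genes[i], genes[i + 1]) < max_gap_bp for i in range(prev, nxt)
    )


def infer_substrates(pgc: PGC, catalog: SeedCatalog) -> set[str]:
    """Majority-vote substrate inference over a PGC's PUP genes.

    Each PUP gene votes once per distinct substrate across its families;
    the substrate(s) with the most votes are returned (ties give all tied
    substrates).  Genes whose families carry no substrates are excluded
    with a warning.
    """
    votes: Counter[str] = Counter()
    for gene in pgc.genes:
        if not gene.is_pup:
            continue
        substrates: set[str] = set()
        for family_id in gene.family_ids:
            fam = catalog.families.get(family_id)
            if fam is None:
                raise KeyError(f"gene {gene.gene_id}: unknown family {family_id}")
            substrates |= fam.substrates
        if not substrates:
            warnings.warn(
                f"gene {gene.gene_id}: no substrates for families "
                f"{sorted(gene.family_ids)}; excluded from vote",
                stacklevel=2,
            )
            continue
        votes.update(substrates)
    if not votes:
        warnings.warn(f"PGC {pgc.pgc_id}: no substrate votes", stacklevel=2)
        return set()
    top = max(votes.values())
    return {s for s, c in votes.items() if c == top}


@dataclass
class PgcSummary:
    """Aggregate statistics over a set of detected clusters."""

    size_hist: dict[int, int]
    n_pup_total: int
    n_other_total: int
    substrate_hist: dict[str, int]

    @property
    def pup_fraction(self) -> float:
        total = self.n_pup_total + self.n_other_total
        return self.n_pup_total / total if total else 0.0


def pgc_summary(pgcs: Sequence[PGC]) -> PgcSummary:
    """Histogram PGC sizes, PUP/other gene counts, and inferred substrates."""
    size_hist: Counter[int] = Counter(len(p.genes) for p in pgcs)
    substrate_hist: Counter[str] = Counter()
    for p in pgcs:
        substrate_hist.update(p.substrates)
    return PgcSummary(
        size_hist=dict(size_hist),
        n_pup_total=sum(p.n_pup for p in pgcs),
        n_other_total=sum(p.n_other for p in pgcs),
        substrate_hist=dict(substrate_hist),
    )


def write_pgc_table(pgcs: Sequence[PGC], path: str | Path) -> None:
    """Write PGCs as TSV; genes serialize as ``id:start-end:fam1+fam2``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["pgc_id", "contig", "start", "end", "n_pup", "n_other", "genes", "substrates"]
        )
        for p in pgcs:
            genes = ",".join(
                f"{g.gene_id}:{g.start}-{g.end}:{'+'.join(sorted(g.family_ids))}"
                for g in p.genes
            )
            writer.writerow(
                [
                    p.pgc_id,
                    p.contig,
                    p.span[0],
                    p.span[1],
                    p.n_pup,
                    p.n_other,
                    genes,
                    ";".join(sorted(p.substrates)),
                ]
            )


def read_pgc_table(path: str | Path) -> list[PGC]:
    """Read back the TSV written by :func:`write_pgc_table`."""
    pgcs: list[PGC] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            genes = []
            for entry in row["genes"].split(","):
                gene_id, coords, fams = entry.split(":")
                start, end = coords.split("-")
                family_ids = frozenset(f for f in fams.split("+") if f)
                genes.append(
                    GeneFeature(
                        gene_id=gene_id,
                        contig=row["contig"],
                        start=int(start),
                        end=int(end),
                        is_pup=bool(family_ids),
                        family_ids=family_ids,
                    )
                )
            substrates = {s for s in row["substrates"].split(";") if s}
            pgcs.append(
                PGC(
                    pgc_id=row["pgc_id"],
                    contig=row["contig"],
                    genes=tuple(genes),
                    substrates=substrates,
                )
            )
    return pgcs


def write_pgc_bed(pgcs: Sequence[PGC], path: str | Path) -> None:
    """Write PGC spans as BED (0-based half-open conversion of 1-based spans)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pgcs:
            start, end = p.span
            fh.write(f"{p.contig}\t{start - 1}\t{end}\t{p.pgc_id}\n")
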