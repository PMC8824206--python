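"""Genome-level abundance/prevalence statistics and Pfam domain enrichment.

Abundance is the percentage of a genome's proteins that are PUP homologs
(or that sit in PGCs); prevalence is the percentage of genomes in a
taxonomy or geography group carrying at least one such gene.  Domain
enrichment among the non-PUP proteins of PGCs uses an upper-tail
hypergeometric test: with ``N`` background proteins of which ``K`` carry a
domain, the chance that a foreground of ``n`` proteins contains ``k`` or
more carriers is ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

UNKNOWN = "unknown"


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a GTDB-style lineage string into bare rank labels.

    ``"d__Bacteria;p__Firmicutes"`` -> ``("Bacteria", "Firmicutes")``;
    empty ranks become ``"unknown"``.
    """
    labels = []
    for part in lineage.split(";"):
        part = part.strip()
        if "__" in part:
            part = part.split("__", 1)[1]
        labels.append(part if part else UNKNOWN)
    return tuple(labels)


@dataclass(frozen=True)
class GenomeProfile:
    """Per-genome PUP/PGC gene counts with taxonomy and geography labels."""

    genome_id: str
    n_proteins: int
    n_pup: int = 0
    n_pgc_genes: int = 0
    lineage: tuple[str, ...] = ()
    continent: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError(f"genome {self.genome_id}: n_proteins must be positive")
        if not (0 <= self.n_pup <= self.n_proteins):
            raise ValueError(f"genome {self.genome_id}: n_pup out of range")
        if not (0 <= self.n_pgc_genes <= self.n_proteins):
            raise ValueError(f"genome {self.genome_id}: n_pgc_genes out of range")

    @property
    def phylum(self) -> str:
        return self.lineage[1] if len(self.lineage) > 1 else UNKNOWN


def _count(profile: GenomeProfile, numerator: str) -> int:
    if numerator == "pup":
        return profile.n_pup
    if numerator == "pgc_genes":
        return profile.n_pgc_genes
    raise ValueError(f"numerator must be 'pup' or 'pgc_genes': {numerator!r}")


def genome_abundance(profile: GenomeProfile, numerator: str = "pup") -> float:
    """Percent of the genome's proteins counted by *numerator*."""
    return 100.0 * _count(profile, numerator) / profile.n_proteins


def _group_key(profile: GenomeProfile, group_by: str) -> str:
    if group_by == "phylum":
        return profile.phylum
    if group_by == "continent":
        return profile.continent or UNKNOWN
    raise ValueError(f"group_by must be 'phylum' or 'continent': {group_by!r}")


def group_prevalence(
    profiles: Sequence[GenomeProfile],
    group_by: str = "phylum",
    indicator: str = "pup",
) -> pd.DataFrame:
    """Per-group percent of genomes with at least one indicated gene.

    Returns a tidy frame with columns group, prevalence_percent, n_genomes.
    Genomes with missing labels fall into the ``"unknown"`` group.
    """
    rows: dict[str, list[int]] = {}
    for p in profiles:
        key = _group_key(p, group_by)
        rows.setdefault(key, []).append(1 if _count(p, indicator) >= 1 else 0)
    records = [
        {
            "group": g,
            "prevalence_percent": 100.0 * sum(flags) / len(flags),
            "n_genomes": len(flags),
        }
        for g, flags in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["group", "prevalence_percent", "n_genomes"])


def median_bubble_table(
    profiles: Sequence[GenomeProfile], numerator: str = "pup"
) -> pd.DataFrame:
    """Median per-genome abundance per (phylum, continent) cell with ranks.

    Within each phylum, continents are ranked 1 = largest median
    (competition/minimum ranking on ties).  Genomes with an unknown
    continent are excluded; empty cells are omitted.
    """
    records = []
    for p in profiles:
        if (p.continent or UNKNOWN) == UNKNOWN:
            continue
        records.append(
            {
                "phylum": p.phylum,
                "continent": p.continent,
                "percent": genome_abundance(p, numerator),
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["phylum", "continent", "median_percent", "rank", "n_genomes"]
        )
    df = pd.DataFrame(records)
    cells = (
        df.groupby(["phylum", "continent"])["percent"]
        .agg(median_percent="median", n_genomes="size")
        .reset_index()
    )
    cells["rank"] = (
        cells.groupby("phylum")["median_percent"]
        .rank(method="min", ascending=False)
        .astype(int)
    )
    return cells[["phylum", "continent", "median_percent", "rank", "n_genomes"]]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one domain in the foreground protein set."""

    domain_name: str
    fg_count: int  # k: foreground proteins carrying the domain
    fg_size: int  # n
    bg_count: int  # K: background proteins carrying the domain
    bg_size: int  # N
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (0 <= self.fg_count <= min(self.fg_size, self.bg_count)):
            raise ValueError(f"{self.domain_name}: inconsistent counts")
        if self.fg_size > self.bg_size or self.bg_count > self.bg_size:
            raise ValueError(f"{self.domain_name}: foreground exceeds background")


def hypergeom_upper_tail(k, N: int, K: int, n: int):
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    *k* may be a scalar or an array of counts; the survival function is
    clipped into (0, 1] to guard against floating round-up.
    """
    p = np.minimum(1.0, hypergeom.sf(np.asarray(k) - 1, N, K, n))
    return float(p) if p.ndim == 0 else p


def enrich_domains(
    fg_proteins: Mapping[str, set[str]],
    bg_proteins: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Test each foreground domain for over-representation vs the background.

    Counting is per protein: a protein with several copies of a domain
    counts once.  Results carry raw upper-tail p-values and
    Benjamini-Hochberg adjusted values, sorted by foreground occurrence
    (descending), ties by raw p then name.
    """
    extra = set(fg_proteins) - set(bg_proteins)
    if extra:
        raise ValueError(
            f"foreground proteins missing from background: {sorted(extra)[:5]}"
        )
    n = len(fg_proteins)
    N = len(bg_proteins)
    fg_domains = sorted({d for doms in fg_proteins.values() for d in doms})
    if not fg_domains:
        return []
    ks = [sum(1 for doms in fg_proteins.values() if d in doms) for d in fg_domains]
    Ks = [sum(1 for doms in bg_proteins.values() if d in doms) for d in fg_domains]
    ps = [hypergeom_upper_tail(k, N, K, n) for k, K in zip(ks, Ks)]
    _, p_adj, _, _ = multipletests(ps, method="fdr_bh")
    results = [
        EnrichmentResult(
            domain_name=d,
            fg_count=k,
            fg_size=n,
            bg_count=K,
            bg_size=N,
            p_value=p,
            p_adjusted=float(q),
        )
        for d, k, K, p, q in zip(fg_domains, ks, Ks, ps, p_adj)
    ]
    results.sort(key=lambda r: (-r.fg_count, r.p_value, r.domain_name))
    return results


def read_genome_metadata(path: str | Path) -> list[GenomeProfile]:
    """Read a genome metadata TSV into profiles.

    Expected columns: genome_id, n_proteins, n_pup, n_pgc_genes, lineage
    (GTDB-style), continent.  Missing count columns default to zero.
    """
    profiles = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            profiles.append(
                GenomeProfile(
                    genome_id=row["genome_id"],
                    n_proteins=int(row["n_proteins"]),
                    n_pup=int(row.get("n_pup") or 0),
                    n_pgc_genes=int(row.get("n_pgc_genes") or 0),
                    lineage=parse_lineage(row.get("lineage") or ""),
                    continent=(row.get("continent") or UNKNOWN).strip() or UNKNOWN,
                )
            )
    return profiles


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    """Write enrichment results as TSV: domain, count, p, p_adj."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["domain", "fg_count", "fg_size", "bg_count", "bg_size", "p_value", "p_adjusted"])
        for r in results:
            writer.writerow(
                [r.domain_name, r.fg_count, r.fg_size, r.bg_count, r.bg_size,
                 f"{r.p_value:.6g}", f"{r.p_adjusted:.6g}"]
            )
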