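"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pupminer import annotate as ann_mod
from pupminer.catalog import SeedCatalog, PupFamily, load_catalog
from pupminer.pgc import GeneFeature


@pytest.fixture(scope="session")
def packaged_catalog() -> SeedCatalog:
    return load_catalog()


def make_catalog(families: dict[str, tuple[set[str], set[str]]]) -> SeedCatalog:
    """Build a small catalog: family_id -> (signature_domains, substrates)."""
    cat = SeedCatalog()
    for fid, (signature, substrates) in families.items():
        cat.families[fid] = PupFamily(
            family_id=fid,
            enzyme_class="".join(c for c in fid if c.isalpha()),
            signature_domains=frozenset(signature),
            n_seeds=1,
            substrates=set(substrates),
        )
    return cat


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    families: set[str] | None = None,
    contig: str = "c",
) -> GeneFeature:
    fams = frozenset(families or ())
    return GeneFeature(
        gene_id=gene_id,
        contig=contig,
        start=start,
        end=end,
        is_pup=bool(fams),
        family_ids=fams,
    )


def random_contig(rng: np.random.Generator, max_genes: int = 50) -> list[GeneFeature]:
    """Random gene layout with gaps straddling the 1 kb rule boundary."""
    n = int(rng.integers(2, max_genes + 1))
    cursor = 1
    genes = []
    for i in range(n):
        length = int(rng.integers(100, 2000))
        start, end = cursor, cursor + length - 1
        is_pup = rng.random() < 0.4
        genes.append(
            GeneFeature(
                gene_id=f"g{i}",
                contig="c",
                start=start,
                end=end,
                is_pup=is_pup,
                family_ids=frozenset({"FR1"}) if is_pup else frozenset(),
            )
        )
        cursor = end + 1 + int(rng.integers(0, 2000))
    return genes


def brute_force_pgc_windows(
    genes: list[GeneFeature], max_between: int = 3, max_gap_bp: int = 1000
) -> set[tuple[int, int]]:
    """Enumerate every gene window, test the three rules, keep maximal ones.

    Returns (first_index, last_index) pairs over the sorted gene list; the
    boundary genes of a window must be PUP genes.
    """

    def window_valid(i: int, j: int) -> bool:
        window = genes[i : j + 1]
        if not (window[0].is_pup and window[-1].is_pup):
            return False
        pup_pos = [k for k, g in enumerate(window) if g.is_pup]
        if len(pup_pos) < 2:
            return False
        if any(b - a - 1 > max_between for a, b in zip(pup_pos, pup_pos[1:])):
            return False
        return all(
            max(0, b.start - a.end - 1) < max_gap_bp
            for a, b in zip(window, window[1:])
        )

    valid = {
        (i, j)
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
        if window_valid(i, j)
    }
    return {
        (i, j)
        for (i, j) in valid
        if not any((oi, oj) != (i, j) and oi <= i and j <= oj for (oi, oj) in valid)
    }


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exhaustive-enumeration upper-tail oracle using integer binomials."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, kk) * math.comb(N - K, n - kk)
        for kk in range(k, min(n, K) + 1)
        if n - kk <= N - K
    )
    return total / denom


def annotate_pipeline(domtbl_path, catalog: SeedCatalog):
    """Run parse -> filter (homolog) -> overlap resolution -> assignment."""
    with open(domtbl_path, encoding="utf-8") as fh:
        hits = ann_mod.parse_domain_hits(fh)
    kept = ann_mod.filter_hits(hits, mode="homolog")
    per_protein: dict[str, list] = {}
    for h in kept:
        per_protein.setdefault(h.protein_id, []).append(h)
    resolved = {p: ann_mod.resolve_overlaps(hs) for p, hs in per_protein.items()}
    return ann_mod.assign_families(resolved, catalog)
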