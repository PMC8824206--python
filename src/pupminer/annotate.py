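"""Domain-hit filtering and signature-based PUP family assignment.

Proteins are assigned to PUP families from profile-HMM domain hits
(HMMER ``--domtblout`` tables).  Hits are filtered on E-value and HMM
coverage, overlapping hits on a protein are resolved to the best one, and a
protein is annotated with family *F* when every domain of *F*'s signature
combination is present among its surviving hits.  The two domain-less UC
families are assigned from iterative similarity-search evidence instead.

Thresholds
----------
seed mode      E < 1e-5 and coverage > 0.3  (characterizing seed proteins)
homolog mode   E < 1e-5 and coverage > 0.6  (recruiting database homologs)
UC similarity  E < 0.001 (final-round iterative search hits)

Coverage is the HMM-coordinate span over the HMM length; the inequalities
are strict on both sides.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .catalog import SeedCatalog

logger = logging.getLogger(__name__)

SEED_EVALUE = 1e-5
SEED_COVERAGE = 0.3
HOMOLOG_EVALUE = 1e-5
HOMOLOG_COVERAGE = 0.6
UC_EVALUE = 1e-3

_COVERAGE_BY_MODE = {"seed": SEED_COVERAGE, "homolog": HOMOLOG_COVERAGE}

#: minimum whitespace-separated fields in a per-domain table row
#: (the trailing free-text description is optional)
_DOMTBL_MIN_FIELDS = 22


class DomtblParseError(ValueError):
    """Malformed per-domain tabular input."""


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit on a protein.

    Coordinates are 1-based inclusive; ``evalue`` is the per-domain
    independent E-value.
    """

    protein_id: str
    domain_name: str
    evalue: float
    hmm_from: int
    hmm_to: int
    hmm_length: int
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"bad HMM coordinates {self.hmm_from}..{self.hmm_to} "
                f"of length {self.hmm_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(f"bad alignment coordinates {self.ali_from}..{self.ali_to}")

    @property
    def coverage(self) -> float:
        """Fraction of the HMM covered by the hit, in (0, 1]."""
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_length

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class SimilarityEvidence:
    """One similarity-search hit supporting a UC-family assignment."""

    protein_id: str
    family_id: str
    seed_id: str
    evalue: float


@dataclass(frozen=True)
class PupAnnotation:
    """A protein's assignment to one PUP family with its supporting hits."""

    protein_id: str
    family_id: str
    evidence: str  # "signature_domains" | "similarity_search"
    supporting_hits: tuple[DomainHit | SimilarityEvidence, ...]
    multi_family: bool = False

    def best_evalue(self) -> float:
        return min(h.evalue for h in self.supporting_hits)


def parse_domain_hits(stream: IO[str] | Iterable[str]) -> list[DomainHit]:
    """Parse a HMMER per-domain tabular stream (``--domtblout`` dialect).

    Assumes the ``hmmscan`` orientation: the target is the HMM and the query
    the protein.  The per-domain independent E-value is taken as the hit
    E-value; ``#`` comment lines are skipped.
    """
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(None, _DOMTBL_MIN_FIELDS)
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise DomtblParseError(
                f"line {lineno}: expected >= {_DOMTBL_MIN_FIELDS} columns, "
                f"got {len(fields)}"
            )
        try:
            hits.append(
                DomainHit(
                    protein_id=fields[3],
                    domain_name=fields[0],
                    evalue=float(fields[12]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    hmm_length=int(fields[2]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                )
            )
        except ValueError as exc:
            raise DomtblParseError(f"line {lineno}: {exc}") from exc
    return hits


def filter_hits(hits: Sequence[DomainHit], mode: str = "homolog") -> list[DomainHit]:
    """Keep hits with E-value < 1e-5 and coverage above the mode threshold.

    ``mode`` is ``"seed"`` (coverage > 0.3) or ``"homolog"`` (coverage > 0.6);
    input order is preserved and the operation is idempotent.
    """
    if mode not in _COVERAGE_BY_MODE:
        raise ValueError(f"mode must be one of {sorted(_COVERAGE_BY_MODE)}: {mode!r}")
    cov = _COVERAGE_BY_MODE[mode]
    return [h for h in hits if h.evalue < HOMOLOG_EVALUE and h.coverage > cov]


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Drop hits overlapping a better hit by >50% of the shorter alignment.

    All hits must belong to one protein.  Priority is lower E-value, then
    longer alignment, then lexicographically smaller domain name.
    """
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    ranked = sorted(hits, key=lambda h: (h.evalue, -h.ali_length, h.domain_name))
    kept: list[DomainHit] = []
    for cand in ranked:
        conflict = any(
            _overlap(cand, acc) > 0.5 * min(cand.ali_length, acc.ali_length)
            for acc in kept
        )
        if not conflict:
            kept.append(cand)
    kept_ids = {id(h) for h in kept}
    return [h for h in hits if id(h) in kept_ids]


def assign_families(
    protein_hits: Mapping[str, Sequence[DomainHit]],
    catalog: SeedCatalog,
    similarity_hits: Mapping[str, Sequence[SimilarityEvidence]] | None = None,
) -> list[PupAnnotation]:
    """Annotate proteins with every PUP family whose signature they satisfy.

    A protein is assigned family *F* iff each domain in *F*'s signature
    combination occurs among its (already filtered and overlap-resolved)
    hits, in any order.  UC families are assigned from *similarity_hits*
    passing the iterative-search E-value contract (< 0.001).  A protein
    satisfying several signatures receives all of them, flagged
    ``multi_family``.
    """
    annotations: list[PupAnnotation] = []
    similarity_hits = similarity_hits or {}
    for ev_list in similarity_hits.values():
        for ev in ev_list:
            if ev.family_id not in catalog.families:
                raise KeyError(f"unknown family in similarity hits: {ev.family_id}")

    per_protein: dict[str, list[tuple[str, str, tuple]]] = {}
    for protein_id in sorted(protein_hits):
        hits = protein_hits[protein_id]
        present = {h.domain_name for h in hits}
        for family_id in sorted(catalog.families):
            fam = catalog.families[family_id]
            if fam.signature_domains and fam.signature_domains <= present:
                support = tuple(
                    h for h in hits if h.domain_name in fam.signature_domains
                )
                per_protein.setdefault(protein_id, []).append(
                    (family_id, "signature_domains", support)
                )
    for protein_id in sorted(similarity_hits):
        passing = [e for e in similarity_hits[protein_id] if e.evalue < UC_EVALUE]
        for family_id in sorted({e.family_id for e in passing}):
            support = tuple(e for e in passing if e.family_id == family_id)
            per_protein.setdefault(protein_id, []).append(
                (family_id, "similarity_search", support)
            )

    for protein_id in sorted(per_protein):
        assigned = per_protein[protein_id]
        multi = len(assigned) > 1
        if multi:
            logger.warning(
                "protein %s matches %d families: %s",
                protein_id,
                len(assigned),
                ",".join(a[0] for a in assigned),
            )
        for family_id, evidence, support in assigned:
            annotations.append(
                PupAnnotation(
                    protein_id=protein_id,
                    family_id=family_id,
                    evidence=evidence,
                    supporting_hits=support,
                    multi_family=multi,
                )
            )
    return annotations


def write_annotations(annotations: Sequence[PupAnnotation], path: str | Path) -> None:
    """Write annotations as TSV: protein_id, family_id, evidence, domains, best E."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "family_id", "evidence", "domains", "best_evalue"])
        for ann in annotations:
            domains = sorted(
                {
                    h.domain_name
                    for h in ann.supporting_hits
                    if isinstance(h, DomainHit)
                }
            )
            writer.writerow(
                [
                    ann.protein_id,
                    ann.family_id,
                    ann.evidence,
                    "+".join(domains),
                    f"{ann.best_evalue():.3g}",
                ]
            )


def read_annotations(path: str | Path) -> list[PupAnnotation]:
    """Read the annotation TSV written by :func:`write_annotations`.

    Supporting hits are not round-tripped; each row is reconstructed with a
    single placeholder evidence record carrying the best E-value.
    """
    annotations: list[PupAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            placeholder = SimilarityEvidence(
                protein_id=row["protein_id"],
                family_id=row["family_id"],
                seed_id="",
                evalue=float(row["best_evalue"]),
            )
            annotations.append(
                PupAnnotation(
                    protein_id=row["protein_id"],
                    family_id=row["family_id"],
                    evidence=row["evidence"],
                    supporting_hits=(placeholder,),
                )
            )
    return annotations
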