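"""Seed/family catalog for polyphenol utilization proteins (PUPs).

A PUP family is anchored by one or more experimentally characterized seed
proteins and is recognized in new sequence data by a *signature* Pfam domain
or an all-required multidomain combination.  Families are grouped into six
enzyme classes by the first level of the seeds' EC numbers:

=====  ======================================
code   reaction class
=====  ======================================
FR     functional group transfer reactions
OR     oxidation/reduction reactions
HR     hydrolysis reactions
NCR    nonhydrolytic cleaving reactions
IR     isomerization reactions
UC     unclassified (seeds without Pfam domains)
=====  ======================================

The packaged catalog (``pupminer/data/pup_families.tsv``) transcribes the
26-family table with per-family homolog counts in Swiss-Prot, TrEMBL and the
unified human gastrointestinal protein catalog (UHGP).  UC families carry no
signature; members are recruited by iterative similarity search instead
(see :mod:`pupminer.annotate`).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

ENZYME_CLASSES: tuple[str, ...] = ("FR", "OR", "HR", "NCR", "IR", "UC")

FAMILY_ID_RE = re.compile(r"^(FR|OR|HR|NCR|IR|UC)([0-9]+)$")

CATALOG_COLUMNS = (
    "family_id",
    "enzyme_class",
    "signature_domains",
    "n_seeds",
    "substrates",
    "swissprot",
    "trembl",
    "uhgp",
)


class CatalogError(ValueError):
    """Malformed or inconsistent catalog input."""


class NoSignatureError(ValueError):
    """Raised when no shared enzymatic domain exists among family members."""


def family_class(family_id: str) -> str:
    """Return the enzyme class code (the alphabetic prefix) of a family id.

    >>> family_class("OR3")
    'OR'
    """
    m = FAMILY_ID_RE.match(family_id)
    if m is None:
        raise CatalogError(f"malformed family id: {family_id!r}")
    return m.group(1)


@dataclass(frozen=True)
class SeedProtein:
    """An experimentally characterized PUP with literature-verified activity."""

    seed_id: str
    organism: str
    family_id: str
    ec_number: str
    domains: tuple[str, ...]
    substrates: frozenset[str]
    products: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.seed_id:
            raise CatalogError("seed_id must be non-empty")
        family_class(self.family_id)  # validates the pattern
        if not self.substrates:
            raise CatalogError(
                f"seed {self.seed_id}: substrates must be non-empty "
                "(seeds require biochemical evidence)"
            )


@dataclass
class PupFamily:
    """A PUP family with its signature domain combination and seed metadata.

    ``signature_domains`` is empty exactly for UC (unclassified) families,
    whose seeds carry no Pfam domain; those families are matched by sequence
    similarity instead.  ``seed_refs`` may be empty when only family-level
    data is available (as in the packaged catalog).
    """

    family_id: str
    enzyme_class: str
    signature_domains: frozenset[str]
    n_seeds: int
    substrates: set[str] = field(default_factory=set)
    seed_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.enzyme_class != family_class(self.family_id):
            raise CatalogError(
                f"family {self.family_id}: enzyme_class {self.enzyme_class!r} "
                "does not match the family-id prefix"
            )
        if (self.enzyme_class == "UC") != (not self.signature_domains):
            raise CatalogError(
                f"family {self.family_id}: signature_domains must be empty "
                "iff the class is UC"
            )
        if self.n_seeds < 0:
            raise CatalogError(f"family {self.family_id}: negative n_seeds")


@dataclass
class SeedCatalog:
    """All PUP families and seeds, plus optional per-family homolog counts.

    ``homolog_counts`` maps family_id -> (swissprot, trembl, uhgp) homolog
    tallies from the reference database searches.
    """

    families: dict[str, PupFamily] = field(default_factory=dict)
    seeds: dict[str, SeedProtein] = field(default_factory=dict)
    homolog_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def signature_index(self) -> dict[frozenset[str], str]:
        """Map each non-empty signature combination to its family id."""
        index: dict[frozenset[str], str] = {}
        for fam in self.families.values():
            if fam.signature_domains:
                index.setdefault(fam.signature_domains, fam.family_id)
        return index

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families.values():
            counts[fam.enzyme_class] = counts.get(fam.enzyme_class, 0) + 1
        return counts


def derive_signature(
    member_domains: Sequence[Sequence[str]],
    enzymatic_allowlist: Iterable[str],
) -> frozenset[str]:
    """Derive a family's signature domain set from its members' architectures.

    Rules, applied after restricting every architecture to enzymatic domains:

    * a single shared single-domain architecture -> that domain;
    * all members share one identical multidomain architecture -> the
      whole combination;
    * members differ but share exactly one domain -> that single domain;
    * members differ and share several domains -> the shared subset.

    Parameters
    ----------
    member_domains
        One ordered Pfam domain list per family member.
    enzymatic_allowlist
        Domain names that count as enzymatic; all others are discarded
        before the rules above are applied.

    Raises
    ------
    NoSignatureError
        If no enzymatic domain is shared by every member.
    """
    if not member_domains:
        raise ValueError("at least one member domain list is required")
    allow = set(enzymatic_allowlist)
    member_sets = [frozenset(d for d in doms if d in allow) for doms in member_domains]
    shared = frozenset.intersection(*member_sets)
    if not shared:
        raise NoSignatureError("no shared enzymatic domain among family members")
    if all(s == member_sets[0] for s in member_sets):
        return member_sets[0]
    if len(shared) == 1:
        return shared
    return shared


def load_allowlist(path: str | Path | None = None) -> frozenset[str]:
    """Read the enzymatic-domain allowlist (packaged default when *path* is None)."""
    if path is None:
        text = (
            resources.files("pupminer.data").joinpath("enzymatic_domains.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    names = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return frozenset(names)


def _parse_int(value: str, column: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise CatalogError(f"line {lineno}: non-integer {column}: {value!r}") from exc


def load_catalog(path: str | Path | None = None) -> SeedCatalog:
    """Load a family catalog TSV (packaged 26-family catalog when *path* is None).

    The TSV carries one family per row with ``+``-joined signature domains
    and ``;``-joined substrate labels; ``#`` lines are comments.  Substrate
    labels are normalized to lowercase.
    """
    if path is None:
        with resources.as_file(
            resources.files("pupminer.data").joinpath("pup_families.tsv")
        ) as p:
            return load_catalog(p)

    catalog = SeedCatalog()
    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(CATALOG_COLUMNS) - set(header)
                if missing:
                    raise CatalogError(
                        f"line {lineno}: missing columns: {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise CatalogError(
                    f"line {lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            family_id = row["family_id"].strip()
            if family_id in catalog.families:
                raise CatalogError(f"line {lineno}: duplicate family_id {family_id!r}")
            signature = frozenset(
                d for d in row["signature_domains"].split("+") if d
            )
            substrates = {
                s.strip().lower() for s in row["substrates"].split(";") if s.strip()
            }
            try:
                fam = PupFamily(
                    family_id=family_id,
                    enzyme_class=row["enzyme_class"].strip(),
                    signature_domains=signature,
                    n_seeds=_parse_int(row["n_seeds"], "n_seeds", lineno),
                    substrates=substrates,
                )
            except CatalogError as exc:
                raise CatalogError(f"line {lineno}: {exc}") from exc
            catalog.families[family_id] = fam
            catalog.homolog_counts[family_id] = (
                _parse_int(row["swissprot"], "swissprot", lineno),
                _parse_int(row["trembl"], "trembl", lineno),
                _parse_int(row["uhgp"], "uhgp", lineno),
            )
    if not catalog.families:
        warnings.warn("catalog has no families", stacklevel=2)
    return catalog


def write_catalog(catalog: SeedCatalog, path: str | Path) -> None:
    """Write a catalog back to the TSV dialect read by :func:`load_catalog`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for family_id in sorted(catalog.families):
            fam = catalog.families[family_id]
            sp, tr, uh = catalog.homolog_counts.get(family_id, (0, 0, 0))
            writer.writerow(
                [
                    fam.family_id,
                    fam.enzyme_class,
                    "+".join(sorted(fam.signature_domains)),
                    fam.n_seeds,
                    ";".join(sorted(fam.substrates)),
                    sp,
                    tr,
                    uh,
                ]
            )


@dataclass
class ValidationReport:
    """Invariant violations plus catalog-wide totals (report-only)."""

    violations: list[str] = field(default_factory=list)
    n_families: int = 0
    n_seeds_total: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    swissprot_total: int = 0
    trembl_total: int = 0
    uhgp_total: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_catalog(catalog: SeedCatalog) -> ValidationReport:
    """Check all catalog invariants and tally totals without raising."""
    report = ValidationReport(
        n_families=len(catalog.families),
        n_seeds_total=sum(f.n_seeds for f in catalog.families.values()),
        class_counts=catalog.class_counts(),
    )
    for sp, tr, uh in catalog.homolog_counts.values():
        report.swissprot_total += sp
        report.trembl_total += tr
        report.uhgp_total += uh

    seen_signatures: dict[frozenset[str], str] = {}
    for fam in catalog.families.values():
        if fam.signature_domains:
            other = seen_signatures.get(fam.signature_domains)
            if other is not None:
                report.violations.append(
                    "duplicate signature "
                    f"{'+'.join(sorted(fam.signature_domains))} shared by "
                    f"families {other} and {fam.family_id}"
                )
            else:
                seen_signatures[fam.signature_domains] = fam.family_id
        if fam.seed_refs and fam.n_seeds != len(fam.seed_refs):
            report.violations.append(
                f"family {fam.family_id}: n_seeds={fam.n_seeds} but "
                f"{len(fam.seed_refs)} seed_refs"
            )
    for seed in catalog.seeds.values():
        if seed.family_id not in catalog.families:
            report.violations.append(
                f"seed {seed.seed_id}: unknown family {seed.family_id}"
            )
    return report
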