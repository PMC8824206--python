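"""Read-level PUP abundance in metagenome samples and group comparisons.

Two abundance measures are supported: the percentage of a sample's reads
whose best translated-search hit against characterized PUPs passes an
E-value cutoff, and RPKM (reads per kilobase of target per million mapped
reads) for reads mapped back to PUP homolog genes.  Group contrasts (e.g.
wet-season vs dry-season samples) use Welch's two-sided t-test.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class SampleAbundance:
    """Per-sample read totals and per-target mapped counts.

    ``per_target`` maps target_id -> (read_count, target_length_bp).
    """

    sample_id: str
    group: str
    total_reads: int
    mapped_reads: int
    per_target: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: total_reads must be positive")
        if not (0 <= self.mapped_reads <= self.total_reads):
            raise ValueError(f"sample {self.sample_id}: mapped_reads out of range")
        for target, (count, length) in self.per_target.items():
            if length <= 0:
                raise ValueError(f"target {target}: non-positive length")
            if count < 0:
                raise ValueError(f"target {target}: negative count")


def percent_reads_mapped(
    hits: pd.DataFrame | Iterable[tuple[str, str, float]],
    total_reads: int,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> float:
    """Percent of reads whose best (lowest-E) hit passes the cutoff.

    *hits* rows are (read_id, target_id, evalue); a read with several hits
    is counted at most once, by its best hit.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame(hits, columns=["read_id", "target_id", "evalue"])
    if hits.empty:
        return 0.0
    best = hits.groupby("read_id")["evalue"].min()
    n_pass = int((best < evalue_cutoff).sum())
    return 100.0 * n_pass / total_reads


def rpkm(read_count: int, target_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of target per million mapped reads."""
    if target_length_bp <= 0:
        raise ValueError("target_length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return read_count / ((target_length_bp / 1_000) * (total_mapped / 1_000_000))


def per_target_rpkm(sample: SampleAbundance) -> dict[str, float]:
    """RPKM per target, normalized by the sample's mapped-read total."""
    return {
        t: rpkm(count, length, sample.mapped_reads)
        for t, (count, length) in sorted(sample.per_target.items())
    }


def aggregate_rpkm(
    sample: SampleAbundance,
    target_to_family: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Sum per-target RPKM per family (or one ``"total"`` entry when unmapped)."""
    values = per_target_rpkm(sample)
    if target_to_family is None:
        return {"total": sum(values.values())}
    out: dict[str, float] = {}
    for target, v in values.items():
        fam = target_to_family.get(target, "unassigned")
        out[fam] = out.get(fam, 0.0) + v
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group Welch t-test outcome with a significance label."""

    t_statistic: float
    p_value: float
    label: str
    n_a: int
    n_b: int


def significance_label(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "n.s."


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided t-test between two groups of per-sample abundances.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    pooled-variance variant.  Identical constant groups yield t = 0 and
    "n.s.".
    """
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; the
        # degenerate case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(values_a, values_b, equal_var=equal_var)
    t = float(t)
    p = float(p)
    if pd.isna(t):  # zero variance in both groups and equal means
        t, p = 0.0, 1.0
    return ComparisonResult(
        t_statistic=t,
        p_value=p,
        label=significance_label(p),
        n_a=len(values_a),
        n_b=len(values_b),
    )


def parse_idxstats(stream: IO[str] | Iterable[str]) -> dict[str, tuple[int, int]]:
    """Parse ``samtools idxstats`` output into target -> (mapped, length).

    Rows are (reference, length, mapped, unmapped); the ``*`` unmapped
    pseudo-reference is skipped.
    """
    out: dict[str, tuple[int, int]] = {}
    for raw in stream:
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 4 or fields[0] == "*":
            continue
        out[fields[0]] = (int(fields[2]), int(fields[1]))
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, group, total_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_count_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a count TSV (target_id, length_bp, count) into a per-target map."""
    out: dict[str, tuple[int, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["target_id"]] = (int(row["count"]), int(row["length_bp"]))
    return out
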