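"""Readers and writers for the pipeline's plain-text formats.

Four dialects are handled:

* **association summary** — whitespace/tab-delimited per-SNP table with
  columns ``SNP CHR BP P`` (header optional; detected by attempting a
  numeric parse of the last field of the first row);
* **gene ranges** — PLINK "glist" dialect, four whitespace-separated
  columns ``CHR START END NAME`` with 1-based inclusive coordinates;
* **gene sets** — GMT: tab-delimited, ``set_id<TAB>description<TAB>member...``;
* **result tables** — TSV mirroring the published per-gene result layout
  (gene, per-method p-values, Fisher statistic, combined p, selection flags).

Parsers validate every row and raise :class:`ParseError` naming the line;
rows are never silently dropped.  Chromosome labels are normalized by
stripping a leading ``chr`` prefix so that ``chr6`` and ``6`` compare equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ParseError",
    "SnpAssocRecord",
    "GeneRegion",
    "GeneSetCollection",
    "normalize_chrom",
    "read_assoc",
    "write_assoc",
    "read_gene_ranges",
    "write_gene_ranges",
    "read_gmt",
    "write_gmt",
    "write_results_table",
    "read_results_table",
    "write_gene_results",
    "read_gene_results",
]


class ParseError(ValueError):
    """A malformed row in one of the supported text formats."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix from a chromosome label."""
    return label[3:] if label.lower().startswith("chr") else label


@dataclass(frozen=True)
class SnpAssocRecord:
    """One SNP's identifier, location and association p-value."""

    snp_id: str
    chrom: str
    pos: int
    p: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of range (0, 1]: {self.p}")


@dataclass(frozen=True)
class GeneRegion:
    """A named gene interval, 1-based inclusive on both ends."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start {self.start} > end {self.end}")

    @property
    def span(self) -> str:
        return f"chr{self.chrom}:{self.start}..{self.end}"


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT contents)."""

    sets: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for set_id, _name, members in self.sets:
            if set_id in seen:
                raise ValueError(f"duplicate set id: {set_id}")
            seen.add(set_id)
            if not members:
                raise ValueError(f"gene set {set_id} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# association summary table
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _looks_like_header(fields: Sequence[str]) -> bool:
    try:
        float(fields[-1])
    except ValueError:
        return True
    return False


def read_assoc(path: str | Path) -> list[SnpAssocRecord]:
    """Read a per-SNP association summary table.

    Columns: SNP id, chromosome, base-pair position, p-value.  A header
    row is detected by a non-numeric final field and skipped.  Duplicate
    SNP ids and p-values outside (0, 1] are rejected.
    """
    records: list[SnpAssocRecord] = []
    seen: set[str] = set()
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split()
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected columns SNP CHR BP P, got {len(fields)} fields")
        snp_id, chrom, bp, p_str = fields[0], fields[1], fields[2], fields[3]
        try:
            pos = int(bp)
            p = float(p_str)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if not (0.0 < p <= 1.0):
            raise ParseError(f"{path}:{lineno}: p-value out of range (0, 1]: {p_str}")
        if snp_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        try:
            records.append(SnpAssocRecord(snp_id, normalize_chrom(chrom), pos, p))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_assoc(records: Iterable[SnpAssocRecord], path: str | Path) -> None:
    """Write an association summary table (exact round-trip precision)."""
    with open(path, "w") as fh:
        fh.write("SNP\tCHR\tBP\tP\n")
        for rec in records:
            fh.write(f"{rec.snp_id}\t{rec.chrom}\t{rec.pos}\t{rec.p:.17g}\n")


# ---------------------------------------------------------------------------
# gene ranges (glist dialect)
# ---------------------------------------------------------------------------

def read_gene_ranges(path: str | Path) -> list[GeneRegion]:
    """Read a PLINK-style glist file: CHR START END NAME, one gene per row."""
    regions: list[GeneRegion] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected CHR START END NAME, got {len(fields)} fields")
        chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if start > end:
            raise ParseError(f"{path}:{lineno}: start {start} > end {end} for gene {name!r}")
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene name {name!r}")
        seen.add(name)
        regions.append(GeneRegion(name, normalize_chrom(chrom), start, end))
    return regions


def write_gene_ranges(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file; members are deduplicated preserving order."""
    sets: list[tuple[str, str, list[str]]] = []
    for lineno, line in _data_lines(path):
        fields = line.rstrip("\n").split("\t")
        fields = [f for f in fields if f != ""]
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        set_id, name = fields[0], fields[1]
        members: list[str] = []
        seen: set[str] = set()
        for m in fields[2:]:
            if m not in seen:
                seen.add(m)
                members.append(m)
        sets.append((set_id, name, members))
    try:
        return GeneSetCollection(sets)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, name, members in collection:
            fh.write("\t".join([set_id, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# meta result tables
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = (
    "gene", "p_a", "p_b", "fisher_stat", "df", "meta_p",
    "in_intersection", "passes_meta_bonferroni", "passes_stringent", "is_bound",
)


def write_results_table(results, path: str | Path) -> None:
    """Write meta-combination results as TSV, p-values at 3 significant digits.

    The caller must supply rows sorted ascending by combined p-value
    (published-table ordering); unsorted input is an error.
    """
    metas = [r.meta_p for r in results]
    if any(a > b for a, b in zip(metas, metas[1:])):
        raise ValueError("results must be sorted ascending by meta_p")
    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.p_a:.2e}\t{r.p_b:.2e}\t{r.fisher_stat:.6g}\t{r.df}\t"
                f"{r.meta_p:.2e}\t{int(r.in_intersection)}\t{int(r.passes_meta_bonferroni)}\t"
                f"{int(r.passes_stringent)}\t{int(r.is_bound)}\n"
            )


def read_results_table(path: str | Path):
    """Read back a results TSV written by :func:`write_results_table`."""
    from .meta_combine import MetaGeneResult  # local import avoids cycle at import time

    results = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RESULT_COLUMNS:
            raise ParseError(f"{path}: unexpected results header {header}")
        for lineno, raw in enumerate(fh, start=2):
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(_RESULT_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_RESULT_COLUMNS)} fields")
            results.append(MetaGeneResult(
                gene=f[0], p_a=float(f[1]), p_b=float(f[2]),
                fisher_stat=float(f[3]), df=int(f[4]), meta_p=float(f[5]),
                in_intersection=bool(int(f[6])), passes_meta_bonferroni=bool(int(f[7])),
                passes_stringent=bool(int(f[8])), is_bound=bool(int(f[9])),
            ))
    return results


# ---------------------------------------------------------------------------
# per-method gene test tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("gene", "nsnps", "stat", "nsims", "p", "bound")


def write_gene_results(results, path: str | Path) -> None:
    """Write per-gene test results (one method) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.n_snps}\t{r.observed_stat:.6g}\t{r.n_sims_used}\t"
                f"{r.empirical_p:.6g}\t{int(r.is_upper_bound)}\n"
            )


def read_gene_results(path: str | Path):
    from .gene_tests import GeneTestResult

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _GENE_COLUMNS:
            raise ParseError(f"{path}: unexpected gene-results header {header}")
        for lineno, raw in enumerate(fh, start=2):
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(_GENE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_GENE_COLUMNS)} fields")
            out.append(GeneTestResult(
                gene=f[0], n_snps=int(f[1]), observed_stat=float(f[2]),
                n_sims_used=int(f[3]), empirical_p=float(f[4]),
                is_upper_bound=bool(int(f[5])),
            ))
    return out
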