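"""Reading, validating and writing GWAS summary-statistics tables.

One row of a summary table describes the additive association of a single
SNP with one trait in one study: the effect and other allele, the
effect-allele frequency (EAF), the per-allele effect size ``beta`` (on the
log-odds scale for binary traits), its standard error, the association
p-value and the study sample size.  The on-disk dialect is tab-separated
with the canonical header ``SNP EA OA EAF BETA SE P N [CHR POS]``; a
``column_map`` lets arbitrary source headers (OpenGWAS exports differ) be
mapped onto these names at read time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import yaml

__all__ = [
    "SummaryRecord",
    "StudyMeta",
    "RowDiagnostic",
    "SummaryTableError",
    "read_summary_table",
    "write_summary_table",
    "read_study_meta",
    "write_study_meta",
    "CANONICAL_HEADER",
    "SMALLEST_POSITIVE_P",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the on-disk dialect.
CANONICAL_HEADER = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "CHR", "POS")

#: Floor for p-values: the smallest positive normal double.  Genome-wide
#: p-values parsed from scientific notation must never underflow to 0,
#: which would violate the 0 < p <= 1 invariant on round-trip.
SMALLEST_POSITIVE_P = 2.2250738585072014e-308


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association summary in one study."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"effect allele {self.effect_allele!r} not one of A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"other allele {self.other_allele!r} not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect allele equals other allele")
        if not (0.0 <= self.eaf <= 1.0) or math.isnan(self.eaf):
            problems.append(f"eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0.0):
            problems.append(f"se {self.se} not > 0")
        if not (0.0 < self.pval <= 1.0):
            problems.append(f"pval {self.pval} outside (0, 1]")
        if not (isinstance(self.n, int) and self.n > 0):
            problems.append(f"n {self.n} not a positive integer")
        if math.isnan(self.beta):
            problems.append("beta is NaN")
        if self.pos is not None and self.pos < 1:
            problems.append(f"pos {self.pos} < 1 (positions are 1-based)")
        return problems

    @property
    def is_valid(self) -> bool:
        return not self.validate()


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata for one GWAS (trait, size, population)."""

    trait_name: str
    n_total: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    n_snps: Optional[int] = None
    population: str = ""

    def validate(self) -> list[str]:
        problems = []
        if self.n_total <= 0:
            problems.append("n_total must be positive")
        if self.n_cases is not None and self.n_controls is not None:
            if self.n_cases + self.n_controls != self.n_total:
                problems.append(
                    f"n_cases + n_controls = {self.n_cases + self.n_controls} "
                    f"!= n_total = {self.n_total}"
                )
        return problems

    @property
    def case_fraction(self) -> Optional[float]:
        if self.n_cases is None:
            return None
        return self.n_cases / self.n_total


class RowDiagnostic(NamedTuple):
    """Why a particular input row was rejected (0-based data row index)."""

    row: int
    snp_id: str
    reason: str


class SummaryTableError(ValueError):
    """Raised when a summary table cannot be read or contains invalid rows."""

    def __init__(self, message: str, diagnostics: Sequence[RowDiagnostic] = ()):
        super().__init__(message)
        self.diagnostics = list(diagnostics)


_DEFAULT_MAP = {name: name for name in CANONICAL_HEADER}


def _parse_float(text: str, what: str) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise ValueError(f"non-numeric {what}: {text!r}") from exc
    return value


def _parse_pval(text: str) -> float:
    value = _parse_float(text, "P")
    if value == 0.0 and text.strip() not in {"0", "0.0"}:
        # underflowed scientific notation such as 1e-400
        return SMALLEST_POSITIVE_P
    return value


def read_summary_table(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
    delimiter: str = "\t",
    on_invalid: str = "raise",
) -> list[SummaryRecord] | tuple[list[SummaryRecord], list[RowDiagnostic]]:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path
        Input file; first line must be a header.
    column_map
        Mapping from canonical names (``SNP``, ``EA``, ...) to the header
        names used in the file.  Defaults to the canonical header itself.
        ``CHR`` and ``POS`` are optional.
    delimiter
        Field separator, tab by default.
    on_invalid
        ``"raise"`` (default) raises :class:`SummaryTableError` listing every
        offending row; ``"report"`` returns ``(records, diagnostics)`` with
        invalid rows excluded but accounted for — rows are never silently
        dropped.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryTableError(f"summary table not found: {path}")
    cmap = dict(_DEFAULT_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SummaryTableError(f"empty file (no header): {path}") from None
        index: dict[str, int] = {}
        for canon in CANONICAL_HEADER:
            source = cmap[canon]
            if source in header:
                index[canon] = header.index(source)
            elif canon not in ("CHR", "POS"):
                raise SummaryTableError(
                    f"missing mapped column {source!r} (for {canon}) in header of {path}"
                )

        records: list[SummaryRecord] = []
        diagnostics: list[RowDiagnostic] = []
        for row_no, row in enumerate(reader):
            if not row or all(not cell.strip() for cell in row):
                continue
            snp_id = row[index["SNP"]].strip()
            try:
                record = SummaryRecord(
                    snp_id=snp_id,
                    effect_allele=row[index["EA"]].strip().upper(),
                    other_allele=row[index["OA"]].strip().upper(),
                    eaf=_parse_float(row[index["EAF"]], "EAF"),
                    beta=_parse_float(row[index["BETA"]], "BETA"),
                    se=_parse_float(row[index["SE"]], "SE"),
                    pval=_parse_pval(row[index["P"]]),
                    n=int(float(row[index["N"]])),
                    chrom=(row[index["CHR"]].strip() or None) if "CHR" in index and len(row) > index["CHR"] else None,
                    pos=(int(row[index["POS"]]) if "POS" in index and len(row) > index["POS"] and row[index["POS"]].strip() else None),
                )
            except (ValueError, IndexError) as exc:
                diagnostics.append(RowDiagnostic(row_no, snp_id, str(exc)))
                continue
            problems = record.validate()
            if problems:
                diagnostics.append(RowDiagnostic(row_no, snp_id, "; ".join(problems)))
            else:
                records.append(record)

    if diagnostics and on_invalid == "raise":
        detail = "; ".join(f"row {d.row} ({d.snp_id}): {d.reason}" for d in diagnostics)
        raise SummaryTableError(f"invalid rows in {path}: {detail}", diagnostics)
    if on_invalid == "report":
        return records, diagnostics
    return records


def _format_float(value: float) -> str:
    # repr round-trips doubles exactly in Python 3
    return repr(float(value))


def write_summary_table(records: Iterable[SummaryRecord], path: str | Path) -> None:
    """Write records as a tab-separated table with the canonical header.

    The write is round-trip stable: ``read(write(x))`` reproduces ``x``
    field-for-field.  ``CHR``/``POS`` columns are emitted only when at least
    one record carries them.
    """
    records = list(records)
    with_positions = any(r.chrom is not None or r.pos is not None for r in records)
    header = CANONICAL_HEADER if with_positions else CANONICAL_HEADER[:8]
    path = Path(path)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row = [
                r.snp_id,
                r.effect_allele,
                r.other_allele,
                _format_float(r.eaf),
                _format_float(r.beta),
                _format_float(r.se),
                _format_float(r.pval),
                str(r.n),
            ]
            if with_positions:
                row += [r.chrom or "", "" if r.pos is None else str(r.pos)]
            writer.writerow(row)


def read_study_meta(path: str | Path) -> StudyMeta:
    """Read a YAML study-metadata sidecar (trait, sizes, population)."""
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    meta = StudyMeta(
        trait_name=payload["trait_name"],
        n_total=int(payload["n_total"]),
        n_cases=int(payload["n_cases"]) if payload.get("n_cases") is not None else None,
        n_controls=int(payload["n_controls"]) if payload.get("n_controls") is not None else None,
        n_snps=int(payload["n_snps"]) if payload.get("n_snps") is not None else None,
        population=payload.get("population", ""),
    )
    problems = meta.validate()
    if problems:
        raise SummaryTableError(f"invalid study metadata in {path}: {'; '.join(problems)}")
    return meta


def write_study_meta(meta: StudyMeta, path: str | Path) -> None:
    payload = {
        "trait_name": meta.trait_name,
        "n_total": meta.n_total,
        "n_cases": meta.n_cases,
        "n_controls": meta.n_controls,
        "n_snps": meta.n_snps,
        "population": meta.population,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)
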