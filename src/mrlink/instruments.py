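"""Instrument selection and strength statistics.

A valid instrumental variant must be strongly associated with the exposure,
independent of the other instruments (LD pruning), and free of direct
associations with known confounders of the exposure-outcome pair.  Strength
is summarised per SNP by the variance explained R^2 = 2 p (1 - p) beta^2 and
the F-statistic F = R^2 (N - K - 1) / (1 - R^2); F > 10 is the conventional
bar for an adequate instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .io import SummaryRecord

__all__ = [
    "LDPair",
    "InstrumentStrength",
    "select_by_pvalue",
    "clump",
    "exclude_confounder_associated",
    "variance_explained",
    "f_statistic",
    "strength_table",
    "read_ld_table",
    "write_ld_table",
    "read_annotation_table",
]


@dataclass(frozen=True)
class LDPair:
    """Squared correlation between two SNPs; symmetric in its arguments."""

    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r_squared: float
    f_stat: float


class ConfounderExclusion(NamedTuple):
    snp_id: str
    trait: str


def select_by_pvalue(
    records: Sequence[SummaryRecord], threshold: float = 5e-8
) -> list[SummaryRecord]:
    """Keep records with association p strictly below ``threshold``.

    The default is the genome-wide significance level 5e-8.  Order is
    preserved.
    """
    return [r for r in records if r.pval < threshold]


def _ld_lookup(ld: Sequence[LDPair]) -> dict[frozenset, float]:
    table: dict[frozenset, float] = {}
    for pair in ld:
        key = frozenset((pair.snp_a, pair.snp_b))
        table[key] = max(table.get(key, 0.0), pair.r2)
    return table


def clump(
    records: Sequence[SummaryRecord],
    ld: Sequence[LDPair],
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> list[SummaryRecord]:
    """Greedy LD clumping over summary statistics.

    Repeatedly take the remaining record with the smallest p-value as an
    index SNP and discard every remaining record on the same chromosome
    within ``window_kb`` of it whose squared correlation with it is at or
    above ``r2_threshold``.  Pairs absent from ``ld`` count as r2 = 0; the
    window is measured from the index SNP's position and is inclusive at the
    boundary.  Ties in p are broken by smaller standard error, then by
    rsID, so the result is deterministic.  Returns the retained index SNPs
    in selection order (ascending p).
    """
    for record in records:
        if record.chrom is None or record.pos is None:
            raise ValueError(
                f"record {record.snp_id} lacks chrom/pos required for windowed clumping"
            )
    lookup = _ld_lookup(ld)
    remaining = sorted(records, key=lambda r: (r.pval, r.se, r.snp_id))
    kept: list[SummaryRecord] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp)
        survivors = []
        for other in remaining:
            same_chrom = other.chrom == index_snp.chrom
            within = same_chrom and abs(other.pos - index_snp.pos) <= window_kb * 1000.0
            r2 = lookup.get(frozenset((index_snp.snp_id, other.snp_id)), 0.0)
            if within and r2 >= r2_threshold:
                continue
            survivors.append(other)
        remaining = survivors
    return kept


def exclude_confounder_associated(
    records: Sequence[SummaryRecord],
    annotations: dict[str, Sequence[str]],
    confounder_traits: Sequence[str],
) -> tuple[list[SummaryRecord], list[ConfounderExclusion]]:
    """Drop SNPs annotated with any listed confounder trait.

    ``annotations`` maps snp_id to zero or more trait labels (e.g. from a
    local PhenoScanner-style export); matching is case-insensitive.  Returns
    the retained records (input order) and the exclusion report.
    """
    confounders = {t.strip().lower() for t in confounder_traits}
    kept: list[SummaryRecord] = []
    removed: list[ConfounderExclusion] = []
    for record in records:
        traits = annotations.get(record.snp_id, ())
        hit = next((t for t in traits if t.strip().lower() in confounders), None)
        if hit is None:
            kept.append(record)
        else:
            removed.append(ConfounderExclusion(record.snp_id, hit))
    return kept, removed


def variance_explained(beta: float, eaf: float) -> float:
    """Variance of the trait explained by one SNP: 2 p (1 - p) beta^2.

    Symmetric in eaf <-> 1 - eaf and invariant to the sign of beta.
    """
    if not 0.0 <= eaf <= 1.0:
        raise ValueError(f"eaf {eaf} outside [0, 1]")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(r_squared: float, n: int, k: int) -> float:
    """Instrument F-statistic: R^2 (N - K - 1) / (1 - R^2).

    ``n`` is the exposure-study sample size and ``k`` the number of
    instruments in the selected set.
    """
    if not 0.0 <= r_squared < 1.0:
        raise ValueError(f"r_squared {r_squared} outside [0, 1)")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    return r_squared * (n - k - 1) / (1.0 - r_squared)


def strength_table(
    records: Sequence[SummaryRecord],
    n: Optional[int] = None,
    k: Optional[int] = None,
) -> list[InstrumentStrength]:
    """Per-SNP R^2 and F for a selected instrument set.

    ``n`` defaults to each record's own sample size and ``k`` to the total
    number of selected instruments.
    """
    k_eff = len(records) if k is None else k
    out = []
    for record in records:
        r2 = variance_explained(record.beta, record.eaf)
        out.append(
            InstrumentStrength(
                snp_id=record.snp_id,
                r_squared=r2,
                f_stat=f_statistic(r2, n if n is not None else record.n, k_eff),
            )
        )
    return out


def read_ld_table(path: str | Path) -> list[LDPair]:
    """Tab-separated LD table: snp_a, snp_b, r2 (header required)."""
    pairs = []
    with open(path) as handle:
        header = handle.readline().strip().split("\t")
        if header[:3] != ["snp_a", "snp_b", "r2"]:
            raise ValueError(f"unexpected LD table header in {path}: {header}")
        for line in handle:
            if not line.strip():
                continue
            a, b, r2 = line.rstrip("\n").split("\t")[:3]
            pairs.append(LDPair(a, b, float(r2)))
    return pairs


def write_ld_table(pairs: Sequence[LDPair], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("snp_a\tsnp_b\tr2\n")
        for pair in pairs:
            handle.write(f"{pair.snp_a}\t{pair.snp_b}\t{repr(pair.r2)}\n")


def read_annotation_table(path: str | Path) -> dict[str, list[str]]:
    """Tab-separated SNP -> trait annotations (one pair per line)."""
    table: dict[str, list[str]] = {}
    with open(path) as handle:
        header = handle.readline().strip().split("\t")
        if header[:2] != ["snp_id", "trait"]:
            raise ValueError(f"unexpected annotation header in {path}: {header}")
        for line in handle:
            if not line.strip():
                continue
            snp_id, trait = line.rstrip("\n").split("\t")[:2]
            table.setdefault(snp_id, []).append(trait)
    return table
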