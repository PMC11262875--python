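"""Place exposure and outcome associations on a common effect allele.

Two GWAS may report the same SNP with the roles of the two alleles swapped,
or report alleles from opposite DNA strands.  Harmonization resolves both so
that the per-SNP exposure effect (gamma_hat) and outcome effect (Gamma_hat)
refer to the same allele.  Palindromic SNPs (A/T or C/G) are strand-ambiguous
from alleles alone; they can be oriented by allele-frequency agreement unless
the frequency is close to 0.5, in which case they are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .io import SummaryRecord

__all__ = [
    "HarmonizedInstrument",
    "Exclusion",
    "harmonize",
    "is_palindromic",
    "write_exclusion_report",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True when the allele pair is its own strand complement (A/T or C/G)."""
    return _COMPLEMENT[allele_a] == allele_b


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure and outcome effects on a shared effect allele.

    ``gamma_hat``/``sigma_x`` are the SNP-exposure effect and its standard
    error; ``Gamma_hat``/``sigma_y`` the SNP-outcome analogues.  ``flipped``
    records whether the outcome effect had to be re-signed to match the
    exposure's effect allele.
    """

    snp_id: str
    gamma_hat: float
    sigma_x: float
    Gamma_hat: float
    sigma_y: float
    eaf_exposure: float
    eaf_outcome: Optional[float] = None
    palindromic: bool = False
    flipped: bool = False
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None

    def __post_init__(self):
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")

    @property
    def wald_ratio(self) -> float:
        return self.Gamma_hat / self.gamma_hat


class Exclusion(NamedTuple):
    snp_id: str
    reason: str


def _check_duplicates(records: Sequence[SummaryRecord], label: str) -> dict[str, SummaryRecord]:
    table: dict[str, SummaryRecord] = {}
    for record in records:
        if record.snp_id in table:
            raise ValueError(f"duplicate snp_id {record.snp_id!r} in {label} study")
        table[record.snp_id] = record
    return table


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindromic_maf_window: float = 0.08,
    strict_palindromic: bool = False,
) -> tuple[list[HarmonizedInstrument], list[Exclusion]]:
    """Match shared SNPs by rsID and orient outcome effects to the exposure
    effect allele.

    Orientation rules, per shared SNP (exposure alleles EA/OA fixed):

    * outcome alleles identical → copy the outcome effect;
    * outcome alleles swapped, or strand-complemented / complement-swapped
      for non-palindromic pairs → same-strand cases copy, swapped cases
      negate the outcome beta and reflect its EAF (``flipped``);
    * palindromic pairs with exposure EAF within ``palindromic_maf_window``
      of 0.5 are excluded (reason ``palindromic-intermediate``); otherwise
      the strand is resolved by frequency agreement: if the two EAFs fall on
      opposite sides of 0.5 the outcome is flipped;
    * any other allele combination is irreconcilable and excluded.

    With ``strict_palindromic`` every palindromic SNP is dropped.

    Returns the harmonized instruments (exposure order) and the exclusion
    report.
    """
    if not 0.0 <= palindromic_maf_window <= 0.5:
        raise ValueError("palindromic_maf_window must lie in [0, 0.5]")
    exposure_by_id = _check_duplicates(exposure, "exposure")
    outcome_by_id = _check_duplicates(outcome, "outcome")

    harmonized: list[HarmonizedInstrument] = []
    excluded: list[Exclusion] = []
    for snp_id, exp in exposure_by_id.items():
        out = outcome_by_id.get(snp_id)
        if out is None:
            excluded.append(Exclusion(snp_id, "missing-in-outcome"))
            continue

        ea, oa = exp.effect_allele, exp.other_allele
        palindromic = is_palindromic(ea, oa)
        if palindromic:
            if strict_palindromic:
                excluded.append(Exclusion(snp_id, "palindromic-strict"))
                continue
            if {out.effect_allele, out.other_allele} != {ea, oa}:
                excluded.append(Exclusion(snp_id, "incompatible-alleles"))
                continue
            if abs(exp.eaf - 0.5) <= palindromic_maf_window:
                excluded.append(Exclusion(snp_id, "palindromic-intermediate"))
                continue
            # The same letter pair represents both strands; orient by
            # frequency agreement.  Put the outcome EAF on the exposure's
            # effect allele first (swap if the letters are reversed), then
            # flip when the frequencies disagree about which allele is minor.
            out_eaf = out.eaf if out.effect_allele == ea else 1.0 - out.eaf
            out_beta = out.beta if out.effect_allele == ea else -out.beta
            flipped = out.effect_allele != ea
            if (exp.eaf < 0.5) != (out_eaf < 0.5):
                out_beta, out_eaf, flipped = -out_beta, 1.0 - out_eaf, not flipped
            harmonized.append(
                HarmonizedInstrument(
                    snp_id=snp_id,
                    gamma_hat=exp.beta,
                    sigma_x=exp.se,
                    Gamma_hat=out_beta,
                    sigma_y=out.se,
                    eaf_exposure=exp.eaf,
                    eaf_outcome=out_eaf,
                    palindromic=True,
                    flipped=flipped,
                    effect_allele=ea,
                    other_allele=oa,
                )
            )
            continue

        pair = (out.effect_allele, out.other_allele)
        if pair == (ea, oa) or pair == (_COMPLEMENT[ea], _COMPLEMENT[oa]):
            flipped = False
            out_beta, out_eaf = out.beta, out.eaf
        elif pair == (oa, ea) or pair == (_COMPLEMENT[oa], _COMPLEMENT[ea]):
            flipped = True
            out_beta, out_eaf = -out.beta, 1.0 - out.eaf
        else:
            excluded.append(Exclusion(snp_id, "incompatible-alleles"))
            continue
        harmonized.append(
            HarmonizedInstrument(
                snp_id=snp_id,
                gamma_hat=exp.beta,
                sigma_x=exp.se,
                Gamma_hat=out_beta,
                sigma_y=out.se,
                eaf_exposure=exp.eaf,
                eaf_outcome=out_eaf,
                palindromic=False,
                flipped=flipped,
                effect_allele=ea,
                other_allele=oa,
            )
        )
    return harmonized, excluded


def write_exclusion_report(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    """Tab-separated exclusion report: snp_id, reason."""
    with open(path, "w") as handle:
        handle.write("snp_id\treason\n")
        for exc in exclusions:
            handle.write(f"{exc.snp_id}\t{exc.reason}\n")
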