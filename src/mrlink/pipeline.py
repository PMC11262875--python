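"""End-to-end orchestration: selection -> clumping -> confounder screen ->
harmonization -> strength statistics -> estimator panel -> diagnostics ->
power, with every output written to a reproducible result bundle."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import diagnostics as diag
from . import estimators as est
from .harmonize import harmonize, write_exclusion_report, Exclusion
from .instruments import (
    clump,
    exclude_confounder_associated,
    read_annotation_table,
    read_ld_table,
    select_by_pvalue,
    strength_table,
)
from .io import read_study_meta, read_summary_table, write_summary_table
from .power import PowerInputs, power_binary

__all__ = ["RunConfig", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Defaults follow the conventional instrument-selection thresholds:
    genome-wide significance 5e-8, clumping at r^2 < 0.001 within a
    10,000 kb window, and a palindromic ambiguity window of 0.08 around
    EAF 0.5.
    """

    exposure_path: str = ""
    outcome_path: str = ""
    ld_path: Optional[str] = None
    annotation_path: Optional[str] = None
    outcome_meta_path: Optional[str] = None
    out_dir: str = "mrlink_results"
    selection_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    palindromic_window: float = 0.08
    confounder_traits: list[str] = field(
        default_factory=lambda: ["coronary artery disease", "hypertension", "body mass index"]
    )
    ivw_effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_significance: float = 0.05
    power_alpha: float = 0.05
    seed: int = 20240715

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in known})


def _estimate_row(e: est.MREstimate) -> dict:
    return {
        "method": e.method,
        "n_snps": e.n_snps,
        "beta": e.beta,
        "se": e.se,
        "pval": e.pval,
        "or": e.or_point,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
    }


def _write_results_table(estimates: Sequence[est.MREstimate], path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("method\tnSNPs\tbeta\tse\tpval\tOR\tCI_low\tCI_high\n")
        for e in estimates:
            handle.write(
                f"{e.method}\t{e.n_snps}\t{e.beta!r}\t{e.se!r}\t{e.pval!r}"
                f"\t{e.or_point!r}\t{e.ci_low!r}\t{e.ci_high!r}\n"
            )


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle to
    ``config.out_dir``.

    Returns a dictionary with the in-memory results (instruments,
    estimates, diagnostics, power).  Two runs with the same config produce
    byte-identical bundles.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "stages": []}

    def stage(name: str, **info):
        log["stages"].append({"stage": name, **info})

    try:
        exposure = read_summary_table(config.exposure_path)
        outcome = read_summary_table(config.outcome_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    stage("read", n_exposure=len(exposure), n_outcome=len(outcome))

    selected = select_by_pvalue(exposure, config.selection_threshold)
    stage("select", threshold=config.selection_threshold, n=len(selected))
    if not selected:
        raise PipelineError(
            "select", f"no instruments at p < {config.selection_threshold!r}"
        )

    if all(r.chrom is not None and r.pos is not None for r in selected):
        ld = read_ld_table(config.ld_path) if config.ld_path else []
        selected = clump(selected, ld, config.clump_r2, config.clump_window_kb)
        stage("clump", r2=config.clump_r2, window_kb=config.clump_window_kb, n=len(selected))
    else:
        stage("clump", skipped="records lack positions")

    confounder_exclusions = []
    if config.annotation_path:
        annotations = read_annotation_table(config.annotation_path)
        selected, confounder_exclusions = exclude_confounder_associated(
            selected, annotations, config.confounder_traits
        )
        stage("confounders", removed=len(confounder_exclusions), n=len(selected))
        if not selected:
            raise PipelineError("confounders", "every instrument was confounder-associated")

    insts, harmonize_exclusions = harmonize(
        selected, outcome, palindromic_maf_window=config.palindromic_window
    )
    stage("harmonize", n=len(insts), excluded=len(harmonize_exclusions))
    if len(insts) < 3:
        raise PipelineError(
            "harmonize", f"only {len(insts)} instruments survived harmonization; need >= 3"
        )
    retained_ids = {i.snp_id for i in insts}
    selected = [r for r in selected if r.snp_id in retained_ids]

    strengths = strength_table(selected)
    r2_total = sum(s.r_squared for s in strengths)
    stage("strength", r2_total=r2_total, f_min=min(s.f_stat for s in strengths))

    try:
        estimates = est.all_estimates(
            insts,
            weighted_median_seed=config.seed,
            bwmr_seed=config.seed + 1,
            n_boot=config.n_boot,
        )
    except est.EstimationError as exc:
        raise PipelineError("estimators", str(exc)) from exc
    stage("estimators", methods=[e.method for e in estimates])

    ivw_fit = next(e for e in estimates if e.method == "ivw")
    egger_pair = (
        next(e for e in estimates if e.method == "egger_slope"),
        next(e for e in estimates if e.method == "egger_intercept"),
    )
    het_ivw = diag.cochran_q(insts, ivw_fit)
    het_egger = diag.cochran_q(insts, egger_pair)
    loo_rows, loo_full = diag.leave_one_out(insts, config.ivw_effects_model)
    radial_result = diag.radial(insts)
    presso_result = (
        diag.presso(
            insts,
            n_sim=config.presso_n_sim,
            seed=config.seed + 2,
            significance=config.presso_significance,
        )
        if len(insts) >= 4
        else None
    )
    stage("diagnostics", q_ivw=het_ivw.q_stat, q_egger=het_egger.q_stat)

    power = None
    if config.outcome_meta_path:
        meta = read_study_meta(config.outcome_meta_path)
        if meta.case_fraction is not None:
            power = power_binary(
                PowerInputs(
                    n_outcome=meta.n_total,
                    case_fraction=meta.case_fraction,
                    r_squared_exposure=r2_total,
                    odds_ratio=ivw_fit.or_point,
                    alpha=config.power_alpha,
                )
            )
            stage("power", power=power)

    # ---- write the bundle -------------------------------------------------
    write_summary_table(selected, out / "instruments.tsv")
    with open(out / "strength.tsv", "w") as handle:
        handle.write("snp_id\tr_squared\tf_stat\n")
        for s in strengths:
            handle.write(f"{s.snp_id}\t{s.r_squared!r}\t{s.f_stat!r}\n")
    _write_results_table(estimates, out / "results.tsv")
    with open(out / "results.json", "w") as handle:
        json.dump([_estimate_row(e) for e in estimates], handle, indent=1, sort_keys=True)

    diagnostics_payload = {
        "heterogeneity": [dataclasses.asdict(het_ivw), dataclasses.asdict(het_egger)],
        "leave_one_out": {
            "reference": _estimate_row(loo_full),
            "rows": [{"snp_id": sid, **_estimate_row(e)} for sid, e in loo_rows],
        },
        "presso": (
            None
            if presso_result is None
            else {
                "global_rss": presso_result.global_rss,
                "global_pval": presso_result.global_pval,
                "outlier_pvals": presso_result.outlier_pvals,
                "outliers": presso_result.outliers,
                "distortion_pval": presso_result.distortion_pval,
                "n_sim": presso_result.n_sim,
                "seed": presso_result.seed,
            }
        ),
        "power": power,
        "r_squared_total": r2_total,
    }
    with open(out / "diagnostics.json", "w") as handle:
        json.dump(diagnostics_payload, handle, indent=1, sort_keys=True)
    diag.write_radial_table(radial_result, out / "radial.tsv")
    exclusions = [Exclusion(e.snp_id, f"confounder:{e.trait}") for e in confounder_exclusions]
    exclusions += harmonize_exclusions
    write_exclusion_report(exclusions, out / "exclusions.tsv")
    with open(out / "run_log.yaml", "w") as handle:
        yaml.safe_dump(log, handle, sort_keys=True)

    return {
        "instruments": selected,
        "harmonized": insts,
        "strengths": strengths,
        "estimates": estimates,
        "heterogeneity": [het_ivw, het_egger],
        "leave_one_out": (loo_rows, loo_full),
        "radial": radial_result,
        "presso": presso_result,
        "power": power,
        "r_squared_total": r2_total,
    }
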