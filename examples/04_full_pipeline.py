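"""The whole pipeline on files, exactly as the command line drives it.

Writes a synthetic exposure/outcome pair to disk, then runs selection ->
clumping -> harmonization -> estimation -> diagnostics -> power through the
pipeline API, producing the same result bundle as `mrlink run`.
"""

import json
import tempfile
from pathlib import Path

from mrlink import RunConfig, run, write_summary_table, write_study_meta, StudyMeta
from mrlink.instruments import write_ld_table
from mrlink.simulate import SimConfig, simulate_pair

workdir = Path(tempfile.mkdtemp(prefix="mrlink_example_"))
sim = simulate_pair(SimConfig(n_snps=20, theta=0.2, gamma_sd=0.3, seed=7))
write_summary_table(sim.exposure, workdir / "exposure.tsv")
write_summary_table(sim.outcome, workdir / "outcome.tsv")
write_ld_table(sim.ld, workdir / "ld.tsv")
write_study_meta(StudyMeta("outcome trait", 36_792, 8_180, 28_612), workdir / "meta.yaml")

config = RunConfig(
    exposure_path=str(workdir / "exposure.tsv"),
    outcome_path=str(workdir / "outcome.tsv"),
    ld_path=str(workdir / "ld.tsv"),
    outcome_meta_path=str(workdir / "meta.yaml"),
    out_dir=str(workdir / "results"),
    seed=1,
)
results = run(config)

ivw_fit = next(e for e in results["estimates"] if e.method == "ivw")
print(f"{len(results['harmonized'])} instruments after selection + harmonization")
print(f"IVW: OR {ivw_fit.or_point:.2f} ({ivw_fit.ci_low:.2f}-{ivw_fit.ci_high:.2f}), "
      f"p = {ivw_fit.pval:.3g}  [generating effect was OR = exp(0.2) = 1.22]")
print(f"power at the IVW odds ratio: {results['power']:.1%}")

bundle = sorted(p.name for p in (workdir / "results").iterdir())
print(f"\nresult bundle in {workdir / 'results'}:")
print(" ", "\n  ".join(bundle))
diag = json.loads((workdir / "results" / "diagnostics.json").read_text())
print(f"\nIVW Q p-value: {diag['heterogeneity'][0]['pval']:.3f} "
      "(no heterogeneity expected on clean synthetic data)")
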