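"""Heterogeneity, outlier and influence diagnostics, with a planted outlier.

Takes a clean synthetic instrument set, corrupts one SNP with a large
pleiotropic offset, and shows how Cochran's Q, the radial decomposition,
the resampling outlier test and leave-one-out each expose it.
"""

import dataclasses

from mrlink import cochran_q, harmonize, ivw, leave_one_out, presso, radial
from mrlink.harmonize import HarmonizedInstrument
from mrlink.simulate import SimConfig, simulate_pair

result = simulate_pair(SimConfig(n_snps=20, theta=0.2, seed=42))
insts, _ = harmonize(result.exposure, result.outcome)

# plant a 10-sigma pleiotropic offset on one instrument
victim = insts[5]
insts = list(insts)
insts[5] = dataclasses.replace(victim, Gamma_hat=victim.Gamma_hat + 10 * victim.sigma_y)

het = cochran_q(insts, ivw(insts))
print(f"Cochran's Q = {het.q_stat:.2f} on {het.df} df, p = {het.pval:.4f}, I^2 = {het.i2:.0%}")
print("  (p < 0.05 or I^2 > 75% would indicate heterogeneity)\n")

rad = radial(insts)
flagged = [p.snp_id for p in rad.points if p.outlier_flag]
print(f"radial outliers (Bonferroni chi-square rule): {flagged}")

pres = presso(insts, n_sim=1000, seed=1)
print(f"resampling test: global p = {pres.global_pval:.4f}, outliers = {pres.outliers}")
if pres.distortion_pval is not None:
    print(f"  distortion p = {pres.distortion_pval:.4f} "
          "(is the estimate shifted by the outliers?)")

rows, full = leave_one_out(insts)
shifts = sorted(rows, key=lambda r: abs(r[1].beta - full.beta), reverse=True)
print(f"\nleave-one-out: full-set beta = {full.beta:+.4f}")
for snp_id, est in shifts[:3]:
    print(f"  without {snp_id}: beta = {est.beta:+.4f}")
print("the corrupted SNP should top every list above")
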