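"""End-to-end run on a synthetic cohort: simulate → GWAS → MR.

The generator builds genotypes in Hardy–Weinberg proportions, a nutrient
exposure driven by 50 small SNP effects (≈2% of variance), and an outcome
liability with a true causal effect of −4. Scanning both traits and feeding
the per-SNP estimates to the estimators should recover that effect.
"""

from nutrimr import run_all_methods
from nutrimr.simulate import SimConfig, gwas_scan, simulate_genotypes, simulate_traits
from nutrimr.summary_data import HarmonizedInstrument

cfg = SimConfig(n_subjects=5000, m_snps=50, beta_causal=-4.0, pleiotropy="none", seed=42)
g = simulate_genotypes(cfg)
cohort = simulate_traits(g, cfg)
print(f"{cfg.n_subjects} subjects, {cfg.m_snps} SNPs, "
      f"{int(cohort.case.sum())} incident cases ({cohort.case.mean():.1%})")

exposure_scan = gwas_scan(g, cohort.exposure.to_numpy(), trait_name="intake")
outcome_scan = gwas_scan(g, cohort.liability.to_numpy(), trait_name="liability")
instruments = [
    HarmonizedInstrument(snp_id=s, bx=exposure_scan[s].beta, sx=exposure_scan[s].se,
                         by=outcome_scan[s].beta, sy=outcome_scan[s].se)
    for s in exposure_scan.records
]

print(f"\ntrue causal effect: {cfg.beta_causal}")
for est in run_all_methods(instruments, seed=0, n_boot=1000):
    print(f"  {est.method:<26s} beta {est.beta:7.3f}  se {est.se:.3f}")

# IVW, radial and the medians land near −4 within sampling error; Egger is
# far noisier in this weak-instrument regime (its SE is ~2x the IVW SE) and
# can wander on a single realization. With pleiotropy="balanced" or
# "directional" in the config, IVW degrades first while the medians stay
# closer to the truth.
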