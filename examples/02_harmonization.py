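"""Align exposure and outcome summary statistics to a common effect allele.

Harmonization resolves swapped allele labels (sign flip + frequency
complement) and strand flips (base complement), and drops palindromic
A/T / C/G variants whose allele frequency is too close to 0.5 to resolve
the strand.
"""

from nutrimr.summary_data import SnpAssociation, SummaryStats, harmonize

exposure = SummaryStats("nutrient intake")
outcome = SummaryStats("incident CKD")

rows = [
    # snp,        ea, oa, eaf,  exposure beta, outcome alleles + beta
    ("rs_aligned", "A", "G", 0.30, 0.020, ("A", "G", -0.10, 0.70)),
    ("rs_swapped", "A", "G", 0.30, 0.020, ("G", "A", -0.10, 0.70)),
    ("rs_strand", "A", "G", 0.30, 0.020, ("T", "C", -0.10, 0.30)),
    ("rs_palin50", "A", "T", 0.50, 0.020, ("A", "T", -0.10, 0.50)),
]
for snp, ea, oa, eaf, bx, (oea, ooa, by, oeaf) in rows:
    exposure.add(SnpAssociation(snp, "1", 1000, ea, oa, eaf, bx, 0.004, 1e-6))
    outcome.add(SnpAssociation(snp, "1", 1000, oea, ooa, oeaf, by, 0.09, 0.3))

instruments, exclusions = harmonize(exposure, outcome, intermediate_af_band=(0.40, 0.60))

for inst in instruments:
    print(f"{inst.snp_id:<11s} bx {inst.bx:+.3f}  by {inst.by:+.3f}")
for e in exclusions:
    print(f"{e['snp_id']:<11s} excluded: {e['reason']}")

# rs_swapped's outcome beta flips to +0.10 (its labels named the other
# allele); rs_strand aligns after complementing; the palindromic SNP at
# EAF 0.50 is unresolvable and is dropped with a reason code.
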