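"""In-silico bisulfite PCR: locate the assay's primer pairs and enumerate CpGs.

Builds the synthetic stand-in promoter reference, predicts each published
amplicon on the appropriately converted strand and lists the CpG registry of
the sequencing amplicon.
"""

from qbgs.mgmt import STUDY_PRIMERS, study_cpg_map, synthetic_mgmt_reference
from qbgs.reference import apply_exclusions, predict_amplicon

ref = synthetic_mgmt_reference()
print(f"reference: {ref.name}, {len(ref)} bp\n")

for name, assumption in [
    ("msp_unmethylated", "fully_unmethylated"),
    ("msp_methylated", "fully_methylated"),
    ("qbgs_second_round", "fully_methylated"),
    ("miseq_second_round", "fully_methylated"),
]:
    amp = predict_amplicon(ref, STUDY_PRIMERS[name], assumption)
    print(f"{name:20s} {amp.start:4d}-{amp.end:4d}  {amp.length:4d} bp")

amp, cmap = study_cpg_map(ref)
print(f"\nqBGS amplicon carries {cmap.n_sites} CpG sites (labels CpG1..CpG{cmap.n_sites})")
analyzed = apply_exclusions(cmap, [1])
print(f"after excluding the site outside the CpG island: {analyzed.n_analyzed} analyzed")
# The amplicon lengths are the assay's published fragment sizes; the CpG
# registry is the coordinate backbone every later module addresses sites by.
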