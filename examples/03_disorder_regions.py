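"""Intragenic comparison: disordered versus structured region codon bias.

Generates genes whose structured segments carry planted codon selection
while disordered segments are neutral, segments each protein at the 0.50
disorder cutoff, computes region-level ΔENC and summarizes the contrast
with Cliff's Δ. A positive Δ for structured-vs-IDR ΔENC reproduces the
expected direction: codon bias concentrates in folded domains.
"""

import numpy as np

from codonatlas import (
    compare_groups,
    extract_region_cds,
    generate_disordered_gene,
    region_metrics,
    segment_regions,
)

idr_delta, structured_delta = [], []
for i in range(100):
    record, profile = generate_disordered_gene(
        idr_fraction=0.4, strength_structured=2.5, strength_idr=0.0,
        n_codons=300, seed=i, transcript_id=f"ENSSYNT{i:08d}",
    )
    idr_set, structured_set = segment_regions(profile)
    pair = extract_region_cds(record.cds, idr_set, structured_set)
    m_idr, m_structured = region_metrics(pair)
    idr_delta.append(m_idr.delta_enc)
    structured_delta.append(m_structured.delta_enc)

effect = compare_groups(structured_delta, idr_delta)
print(f"median delta_enc  IDR: {np.median(idr_delta):6.2f}   "
      f"structured: {np.median(structured_delta):6.2f}")
print(f"Cliff's delta (structured vs IDR): {effect.delta:.3f} "
      f"[{effect.ci_low:.3f}, {effect.ci_high:.3f}] ({effect.magnitude}), "
      f"Wilcoxon p = {effect.p_wilcoxon:.3g}")
print("Structured regions show the higher composition-corrected bias, "
      "matching the planted region-differential selection.")
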