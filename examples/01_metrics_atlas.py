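"""Per-gene codon-usage metrics on a small synthetic gene set.

Generates 20 coding sequences under different regimes, computes RSCU-family
behaviour, GC3, Wright's ENC, the GC3-corrected ΔENC and CAI, and prints a
compact atlas. High positive ΔENC marks genes whose codon bias exceeds what
their third-position composition alone predicts.
"""

from codonatlas import (
    build_atlas_table,
    build_cai_weights,
    generate_neutral_transcript,
    generate_selected_transcript,
    pool_counts,
)
from codonatlas.sequence_io import count_codons
from codonatlas.simulate import DEFAULT_OPTIMALITY

records = []
for i in range(10):
    records.append(
        generate_neutral_transcript(
            0.4 + 0.04 * i, 300, seed=i, transcript_id=f"ENSSYNT{i:08d}",
            gene_id=f"ENSSYNG{i:08d}",
        )
    )
for i in range(10, 20):
    records.append(
        generate_selected_transcript(
            DEFAULT_OPTIMALITY, 2.0, 300, seed=i, transcript_id=f"ENSSYNT{i:08d}",
            gene_id=f"ENSSYNG{i:08d}",
        )
    )

cai_weights = build_cai_weights(pool_counts(count_codons(r.cds) for r in records))
atlas = build_atlas_table(records, cai_weights=cai_weights)

print(atlas[["transcript_id", "enc", "gc3", "delta_enc", "cai"]].round(3).to_string(index=False))
print(
    "\nFirst 10 genes are neutral (delta_enc near the small-sample level), "
    "last 10 are under planted selection (low ENC, large positive delta_enc)."
)
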