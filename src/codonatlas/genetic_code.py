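"""Standard nuclear genetic-code tables shared by every metric in the package.

Synonymous families are grouped by amino acid; degeneracy classes follow the
standard code: nine 2-fold families, one 3-fold (Ile), five 4-fold and three
6-fold (Leu, Ser, Arg) families, plus the nondegenerate Met and Trp.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_BASES = "TCAG"

#: All 64 codons in TCAG block order (third position varies fastest).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

STOP_CODONS: tuple[str, str, str] = ("TAA", "TAG", "TGA")

#: Sense codon -> one-letter amino acid, from the standard nuclear table.
CODON_TO_AA: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Amino acid -> synonymous codons, in CODONS order.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in AA_TO_CODONS
}

#: Amino acids with >1 synonymous codon, i.e. the 18 degenerate families.
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa, cods in AA_TO_CODONS.items() if len(cods) > 1
)

SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    aa for aa, cods in AA_TO_CODONS.items() if len(cods) == 1
)  # Met, Trp

#: Degeneracy class (family size) -> member amino acids.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _size in (2, 3, 4, 6):
    DEGENERACY_CLASSES[_size] = tuple(
        aa for aa in DEGENERATE_AAS if len(AA_TO_CODONS[aa]) == _size
    )

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
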