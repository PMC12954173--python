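"""Codon- and tRNA-adaptation indices (CAI and tAI).

CAI follows the Sharp & Li construction: relative adaptiveness weights
w_k = X_k / max_j X_j within each synonymous family, computed here from
pooled transcriptome-wide counts with a +1 pseudocount so unobserved codons
never produce ln 0; a transcript's CAI is the geometric mean of w over its
scorable codons (Met, Trp and stops excluded by convention).

tAI follows dos Reis: each sense codon's absolute weight is
Σ (1 − s) · tGCN over the anticodons that can decode it, combining
Watson–Crick pairing with the four standard wobble channels; weights are
normalized by their maximum, codons with zero weight receive the geometric
mean of the non-zero relative weights, and tAI is the geometric mean of the
per-codon weights over a transcript (Met included, stops excluded).
Inosine-bearing anticodons are identified as genomically A-starting
anticodons.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    revcomp,
)
from .sequence_io import CodonCounts

#: Default wobble penalties (dos Reis et al. standard selective constraints).
#: Watson–Crick channels are unpenalized; the remaining entries are the four
#: wobble channels plus the dedicated Ile ATA channel.
DEFAULT_S: dict[str, float] = {
    "wc": 0.0,       # Watson–Crick third-position pair
    "gu": 0.41,      # anticodon G reading codon-ending T/U
    "ic": 0.28,      # inosine (genomic A) reading codon-ending C
    "ia": 0.9999,    # inosine reading codon-ending A
    "ug": 0.68,      # anticodon U reading codon-ending G
    "ata": 0.89,     # the special ATA (Ile) decoding channel
}

_CAI_EXCLUDED_AAS = frozenset({"M", "W"})


@dataclass
class CaiWeights:
    """Relative adaptiveness per sense codon; max within each family is 1."""

    w: dict[str, float]
    reference_total: int


@dataclass
class TrnaPool:
    """tRNA gene copy number per anticodon (DNA alphabet)."""

    copy_number: dict[str, int] = field(default_factory=dict)


@dataclass
class TaiWeights:
    s: dict[str, float]
    absolute_w: dict[str, float]
    w: dict[str, float]


def build_cai_weights(pooled: CodonCounts) -> CaiWeights:
    """Relative adaptiveness w_k = (X_k + 1)/(max_j X_j + 1) per family."""
    sense_total = sum(
        n for c, n in pooled.counts.items() if c not in STOP_CODONS
    )
    if sense_total == 0:
        raise ValueError("pooled reference counts contain no sense codons")
    w: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        family_max = max(pooled.get(c) for c in codons)
        for c in codons:
            w[c] = (pooled.get(c) + 1) / (family_max + 1)
    return CaiWeights(w=w, reference_total=sense_total)


def compute_cai(counts: CodonCounts, weights: CaiWeights) -> float | None:
    """Geometric mean of w over scorable codons; None if none are scorable."""
    log_sum = 0.0
    n_scored = 0
    for codon, n in counts.counts.items():
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa in _CAI_EXCLUDED_AAS or n == 0:
            continue
        log_sum += n * math.log(weights.w[codon])
        n_scored += n
    if n_scored == 0:
        return None
    return math.exp(log_sum / n_scored)


_GTRNADB_RE = re.compile(r"tRNA-\w{2,3}-([ACGTU]{3})")


def parse_trna_pool(source: str | Path) -> TrnaPool:
    """Parse a tRNA pool from a two-column TSV or a GtRNAdb-style FASTA.

    TSV rows are ``anticodon<TAB>copy_number`` (an optional header line is
    tolerated); copies are aggregated per anticodon. In FASTA mode each
    header encodes one tRNA gene with its isotype-anticodon name
    (``...tRNA-Ala-AGC-1-1``) and contributes one gene copy. Anticodons are
    normalized to the DNA alphabet.
    """
    path = Path(source)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty tRNA pool input")
    copy_number: dict[str, int] = {}
    if lines[0].startswith(">"):
        for ln in lines:
            if not ln.startswith(">"):
                continue
            m = _GTRNADB_RE.search(ln)
            if m:
                anticodon = m.group(1).upper().replace("U", "T")
                copy_number[anticodon] = copy_number.get(anticodon, 0) + 1
    else:
        for ln in lines:
            parts = re.split(r"[\t,\s]+", ln)
            if len(parts) < 2:
                continue
            anticodon = parts[0].upper().replace("U", "T")
            if not re.fullmatch(r"[ACGT]{3}", anticodon):
                continue  # header or malformed row
            n = int(parts[1])
            if n < 0:
                raise ValueError(f"{path}: negative copy number for {anticodon}")
            copy_number[anticodon] = copy_number.get(anticodon, 0) + n
    if not copy_number:
        raise ValueError(f"{path}: no parseable tRNA entries")
    return TrnaPool(copy_number=copy_number)


def decoding_channels(codon: str, s: Mapping[str, float]) -> list[tuple[str, float]]:
    """Anticodons able to decode *codon*, with their wobble penalties.

    The generic scheme pairs the Watson–Crick anticodon (penalty 0) with one
    wobble channel determined by the codon's third base. Three codons are
    special-cased so wobble never crosses an amino-acid or stop boundary
    where the standard rules would: ATG and TGG are decoded only by their
    Watson–Crick anticodons, and ATA only through its dedicated channel.
    """
    if codon == "ATG":
        return [(revcomp(codon), s["wc"])]
    if codon == "TGG":
        return [(revcomp(codon), s["wc"])]
    if codon == "ATA":
        return [(revcomp(codon), s["ata"])]
    prefix, third = codon[:2], codon[2]
    channels = [(revcomp(codon), s["wc"])]
    if third == "T":
        channels.append((revcomp(prefix + "C"), s["gu"]))
    elif third == "C":
        channels.append((revcomp(prefix + "T"), s["ic"]))
    elif third == "A":
        channels.append((revcomp(prefix + "T"), s["ia"]))
    elif third == "G":
        channels.append((revcomp(prefix + "A"), s["ug"]))
    return channels


def build_tai_weights(
    pool: TrnaPool, s: Mapping[str, float] | None = None
) -> TaiWeights:
    """Per-codon decoding weights from tRNA gene copy numbers.

    absolute_w = Σ (1 − s_channel) · tGCN over decoding anticodons; relative
    w = absolute_w / max(absolute_w); zero-weight codons are assigned the
    geometric mean of the non-zero relative weights. Stop codons excluded.
    """
    if not pool.copy_number or not any(pool.copy_number.values()):
        raise ValueError("tRNA pool is empty")
    s = dict(DEFAULT_S if s is None else s)
    absolute: dict[str, float] = {}
    for codon in SENSE_CODONS:
        total = 0.0
        for anticodon, penalty in decoding_channels(codon, s):
            total += (1.0 - penalty) * pool.copy_number.get(anticodon, 0)
        absolute[codon] = total
    max_abs = max(absolute.values())
    if max_abs == 0:
        raise ValueError("all absolute tAI weights are zero for this pool")
    w = {c: a / max_abs for c, a in absolute.items()}
    nonzero = [x for x in w.values() if x > 0]
    gm = math.exp(sum(math.log(x) for x in nonzero) / len(nonzero))
    for c in w:
        if w[c] == 0:
            w[c] = gm
    return TaiWeights(s=s, absolute_w=absolute, w=w)


def compute_tai(counts: CodonCounts, weights: TaiWeights) -> float | None:
    """Geometric mean of decoding weights over all sense codons; None if none."""
    log_sum = 0.0
    n_scored = 0
    for codon, n in counts.counts.items():
        if codon in STOP_CODONS or codon not in weights.w or n == 0:
            continue
        log_sum += n * math.log(weights.w[codon])
        n_scored += n
    if n_scored == 0:
        return None
    return math.exp(log_sum / n_scored)


def write_weights_tsv(w: Mapping[str, float], path: str | Path) -> None:
    """Export a codon→weight mapping as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("codon\tw\n")
        for codon in SENSE_CODONS:
            if codon in w:
                fh.write(f"{codon}\t{w[codon]:.6g}\n")
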