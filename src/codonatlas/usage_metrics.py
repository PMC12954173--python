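"""Per-gene codon-usage metrics: RSCU, GC3, Wright's ENC, expected ENC, ΔENC.

Conventions used throughout: stop codons are excluded from RSCU, GC3, ENC,
CAI and tAI; the terminal stop feeds only :func:`stop_codon_usage`. ENC is
Wright's effective number of codons

    Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

where F̄k is the mean homozygosity of the observed k-fold degenerate
families. Two homozygosity estimators are offered: the plain frequency form
F = Σ p̂², under which the analytic limits 20 (one codon per amino acid) and
61 (uniform synonymous usage) hold exactly, and Wright's small-sample
corrected form F = (nΣp̂² − 1)/(n − 1), which removes the upward bias of the
frequency form on short sequences. ΔENC = ENCexp − ENCobs with

    ENCexp = 2 + GC3 + 29/(GC3² + (1 − GC3)²),

so positive ΔENC marks bias stronger than the gene's third-position
composition alone predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    STOP_CODONS,
)
from .sequence_io import CodonCounts, TranscriptRecord, count_codons

ENC_MIN = 20.0
ENC_MAX = 61.0


@dataclass
class RscuTable:
    """RSCU per codon; codons of unobserved families are absent, not 0."""

    values: dict[str, float]
    family: dict[str, str]


@dataclass
class EncComponents:
    f2bar: float
    f3bar: float
    f4bar: float
    f6bar: float
    nc: float


@dataclass
class UsageMetrics:
    """One atlas row: the full metric set for a transcript or region."""

    gc3: float | None = None
    enc_obs: float | None = None
    enc_exp: float | None = None
    delta_enc: float | None = None
    cai: float | None = None
    tai: float | None = None
    stop_codon: str | None = None


def compute_rscu(counts: CodonCounts) -> RscuTable:
    """Relative synonymous codon usage: X_ij / ((1/n_i) Σ_k X_ik).

    Families with zero observed total are omitted from ``values``; Met and
    Trp, as single-codon families, get RSCU 1 when observed.
    """
    values: dict[str, float] = {}
    family: dict[str, str] = {c: aa for c, aa in CODON_TO_AA.items()}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(counts.get(c) for c in codons)
        if total == 0:
            continue
        expected = total / len(codons)
        for c in codons:
            values[c] = counts.get(c) / expected
    return RscuTable(values=values, family=family)


def compute_gc3(counts: CodonCounts, mode: str = "all_sense") -> float | None:
    """Fraction of included codons whose third base is G or C.

    ``all_sense`` excludes only stop codons; ``gc3s`` additionally excludes
    the nondegenerate ATG and TGG. Returns None when no codon is included.
    """
    if mode not in ("all_sense", "gc3s"):
        raise ValueError(f"unknown GC3 mode: {mode!r}")
    excluded = set(STOP_CODONS)
    if mode == "gc3s":
        excluded |= {"ATG", "TGG"}
    total = 0
    gc = 0
    for codon, n in counts.counts.items():
        if codon in excluded:
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    if total == 0:
        return None
    return gc / total


def compute_enc(
    counts: CodonCounts, estimator: str = "frequency"
) -> EncComponents | None:
    """Wright's effective number of codons from a codon-count table.

    Per observed degenerate family, homozygosity F is estimated with the
    chosen estimator (``frequency`` or ``wright_corrected``; the corrected
    form needs n ≥ 2 and families yielding F ≤ 0 are treated as unobserved).
    Class means are taken over observed families; a missing 3-fold class is
    imputed as (F̄2 + F̄4)/2 and a missing 6-fold class analogously. Nc is
    clamped to [20, 61]. Returns None when no 2-fold or no 4-fold family is
    observed.
    """
    if estimator not in ("frequency", "wright_corrected"):
        raise ValueError(f"unknown ENC estimator: {estimator!r}")
    fam_f: dict[str, float] = {}
    for size, aas in DEGENERACY_CLASSES.items():
        for aa in aas:
            codons = AA_TO_CODONS[aa]
            n = sum(counts.get(c) for c in codons)
            if n == 0:
                continue
            sum_p2 = sum((counts.get(c) / n) ** 2 for c in codons)
            if estimator == "frequency":
                f = sum_p2
            else:
                if n < 2:
                    continue
                f = (n * sum_p2 - 1) / (n - 1)
                if f <= 0:
                    continue
            fam_f[aa] = f
    means: dict[int, float | None] = {}
    for size, aas in DEGENERACY_CLASSES.items():
        observed = [fam_f[aa] for aa in aas if aa in fam_f]
        means[size] = sum(observed) / len(observed) if observed else None
    if means[2] is None or means[4] is None:
        return None
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2
    if means[6] is None:
        means[6] = (means[2] + means[4]) / 2
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    nc = min(ENC_MAX, max(ENC_MIN, nc))
    return EncComponents(
        f2bar=means[2], f3bar=means[3], f4bar=means[4], f6bar=means[6], nc=nc
    )


def expected_enc(gc3: float) -> float:
    """Wright's neutral-expectation curve: 2 + GC3 + 29/(GC3² + (1−GC3)²)."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"GC3 must lie in [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3**2 + (1.0 - gc3) ** 2)


def compute_delta_enc(
    counts: CodonCounts,
    gc3_mode: str = "all_sense",
    estimator: str = "frequency",
) -> float | None:
    """ΔENC = ENCexp(GC3) − ENCobs; None when either side is undefined."""
    gc3 = compute_gc3(counts, mode=gc3_mode)
    enc = compute_enc(counts, estimator=estimator)
    if gc3 is None or enc is None:
        return None
    return expected_enc(gc3) - enc.nc


def stop_codon_usage(records: Sequence[TranscriptRecord]) -> dict[str, float]:
    """Fraction of transcripts terminating in each of TAA, TAG, TGA."""
    if not records:
        raise ValueError("no records supplied")
    tallies = {s: 0 for s in STOP_CODONS}
    for rec in records:
        stop = rec.cds[-3:]
        if stop not in tallies:
            raise ValueError(
                f"{rec.transcript_id}: terminal codon {stop!r} is not a stop codon"
            )
        tallies[stop] += 1
    n = len(records)
    return {s: tallies[s] / n for s in STOP_CODONS}


def transcript_metrics(
    record: TranscriptRecord,
    cai_weights=None,
    tai_weights=None,
    gc3_mode: str = "all_sense",
    estimator: str = "frequency",
) -> UsageMetrics:
    """Full metric row for one QC-passing transcript."""
    from .adaptation import compute_cai, compute_tai

    counts = count_codons(record.cds)
    gc3 = compute_gc3(counts, mode=gc3_mode)
    enc = compute_enc(counts, estimator=estimator)
    enc_exp = expected_enc(gc3) if gc3 is not None else None
    delta = (
        enc_exp - enc.nc if (enc_exp is not None and enc is not None) else None
    )
    cai = compute_cai(counts, cai_weights) if cai_weights is not None else None
    tai = compute_tai(counts, tai_weights) if tai_weights is not None else None
    stop = record.cds[-3:] if record.cds[-3:] in STOP_CODONS else None
    return UsageMetrics(
        gc3=gc3,
        enc_obs=enc.nc if enc is not None else None,
        enc_exp=enc_exp,
        delta_enc=delta,
        cai=cai,
        tai=tai,
        stop_codon=stop,
    )


ATLAS_COLUMNS = [
    "transcript_id",
    "gene_id",
    "gene_symbol",
    "chrom",
    "start",
    "end",
    "enc",
    "gc3",
    "enc_exp",
    "delta_enc",
    "cai",
    "tai",
    "stop_codon",
]


def build_atlas_table(
    records: Sequence[TranscriptRecord],
    cai_weights=None,
    tai_weights=None,
    gc3_mode: str = "all_sense",
    estimator: str = "frequency",
) -> pd.DataFrame:
    """Assemble the per-transcript metric atlas as a DataFrame."""
    rows = []
    for rec in records:
        m = transcript_metrics(
            rec,
            cai_weights=cai_weights,
            tai_weights=tai_weights,
            gc3_mode=gc3_mode,
            estimator=estimator,
        )
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "gene_id": rec.gene_id,
                "gene_symbol": rec.gene_symbol,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "enc": m.enc_obs,
                "gc3": m.gc3,
                "enc_exp": m.enc_exp,
                "delta_enc": m.delta_enc,
                "cai": m.cai,
                "tai": m.tai,
                "stop_codon": m.stop_codon,
            }
        )
    return pd.DataFrame(rows, columns=ATLAS_COLUMNS)


def write_atlas_tsv(atlas: pd.DataFrame, path: str | Path) -> None:
    """Write the atlas with 6-significant-digit floats for stable reruns."""
    atlas.to_csv(path, sep="\t", index=False, float_format="%.6g")
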