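"""Intragenic stratification by structural disorder.

Per-residue disorder probabilities (IUPred3 long-format output or a generic
two-column table) are thresholded at 0.50 — residues scoring ≥ 0.50 are
intrinsically disordered (IDR), the rest structured. Each residue maps back
to its codon, the codons of each class are concatenated in residue order
into two region sub-sequences per transcript (the terminal stop belongs to
neither), and the full metric set is computed independently per region
using the region's own GC3 for its expected ENC. ENC is unstable on very
short sequences, so regions below ``min_codons`` codons get absent
enc/delta_enc while CAI/tAI are still computed from a single codon up.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet

from .sequence_io import CodonCounts, count_codons
from .usage_metrics import (
    UsageMetrics,
    compute_enc,
    compute_gc3,
    expected_enc,
)

DEFAULT_CUTOFF = 0.50
DEFAULT_MIN_CODONS = 20


@dataclass
class DisorderProfile:
    """Ordered per-residue disorder probabilities for one protein."""

    transcript_id: str
    scores: list[float]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class RegionPair:
    """Concatenated codons of disordered and of structured residues."""

    idr_cds: str
    structured_cds: str


def parse_disorder_scores(
    source: str | Path, transcript_id: str | None = None
) -> DisorderProfile:
    """Parse IUPred3 long-format output (or a two-column position/score TSV).

    Comment lines start with '#'. Data lines are whitespace-separated
    ``position residue score`` (IUPred3) or ``position score``. Positions
    must be contiguous from 1; scores must lie in [0, 1].
    """
    path = Path(source)
    if transcript_id is None:
        transcript_id = path.stem
    entries: list[tuple[int, float]] = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) >= 3:
            pos, score = int(parts[0]), float(parts[2])
        elif len(parts) == 2:
            pos, score = int(parts[0]), float(parts[1])
        else:
            raise ValueError(f"{path}: unparseable line {ln!r}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"{path}: score {score} at position {pos} outside [0, 1]")
        entries.append((pos, score))
    if not entries:
        raise ValueError(f"{path}: no residue scores found")
    positions = [p for p, _ in entries]
    if positions != list(range(1, len(entries) + 1)):
        raise ValueError(f"{path}: positions must be contiguous starting at 1")
    return DisorderProfile(transcript_id=transcript_id, scores=[s for _, s in entries])


def segment_regions(
    profile: DisorderProfile, cutoff: float = DEFAULT_CUTOFF
) -> tuple[FrozenSet[int], FrozenSet[int]]:
    """Split residues into (IDR, structured) 1-based index sets.

    The cutoff is inclusive on the disordered side: score ≥ cutoff is IDR.
    """
    if not profile.scores:
        raise ValueError("empty disorder profile")
    idr = frozenset(
        i for i, s in enumerate(profile.scores, start=1) if s >= cutoff
    )
    structured = frozenset(range(1, len(profile.scores) + 1)) - idr
    return idr, structured


def extract_region_cds(
    cds: str,
    idr_set: FrozenSet[int] | set[int],
    structured_set: FrozenSet[int] | set[int],
) -> RegionPair:
    """Concatenate the codons of each residue class into two sub-sequences.

    Residue i (1-based) occupies nucleotides 3(i−1)+1..3i. The index sets
    must partition residues 1..len(cds)/3 − 1; the terminal stop codon is
    assigned to neither class.
    """
    n_res = len(cds) // 3 - 1
    all_residues = set(range(1, n_res + 1))
    union = set(idr_set) | set(structured_set)
    if max(union, default=0) > n_res:
        raise ValueError("residue index beyond protein length")
    if union != all_residues or (set(idr_set) & set(structured_set)):
        raise ValueError("index sets must partition residues 1..protein length")
    idr_codons = [cds[3 * (i - 1): 3 * i] for i in sorted(idr_set)]
    structured_codons = [cds[3 * (i - 1): 3 * i] for i in sorted(structured_set)]
    return RegionPair(
        idr_cds="".join(idr_codons), structured_cds="".join(structured_codons)
    )


def _metrics_for_region(
    region_cds: str,
    cai_weights,
    tai_weights,
    min_codons: int,
    gc3_mode: str,
    estimator: str,
) -> UsageMetrics:
    from .adaptation import compute_cai, compute_tai

    if not region_cds:
        return UsageMetrics()
    counts = count_codons(region_cds)
    gc3 = compute_gc3(counts, mode=gc3_mode)
    enc_obs = enc_exp = delta = None
    if counts.total >= min_codons:
        enc = compute_enc(counts, estimator=estimator)
        if enc is not None and gc3 is not None:
            enc_obs = enc.nc
            enc_exp = expected_enc(gc3)
            delta = enc_exp - enc_obs
    cai = compute_cai(counts, cai_weights) if cai_weights is not None else None
    tai = compute_tai(counts, tai_weights) if tai_weights is not None else None
    return UsageMetrics(
        gc3=gc3, enc_obs=enc_obs, enc_exp=enc_exp, delta_enc=delta,
        cai=cai, tai=tai,
    )


def region_metrics(
    pair: RegionPair,
    cai_weights=None,
    tai_weights=None,
    min_codons: int = DEFAULT_MIN_CODONS,
    gc3_mode: str = "all_sense",
    estimator: str = "frequency",
) -> tuple[UsageMetrics, UsageMetrics]:
    """Full metric set per region: (IDR metrics, structured metrics)."""
    if not pair.idr_cds and not pair.structured_cds:
        raise ValueError("both regions are empty")
    idr = _metrics_for_region(
        pair.idr_cds, cai_weights, tai_weights, min_codons, gc3_mode, estimator
    )
    structured = _metrics_for_region(
        pair.structured_cds, cai_weights, tai_weights, min_codons, gc3_mode, estimator
    )
    return idr, structured


def profile_matches_cds(profile: DisorderProfile, cds: str) -> bool:
    """True when the profile covers exactly the protein of *cds* (stop excluded).

    Mismatches signal upstream inconsistency; the pipeline logs and skips
    such transcripts.
    """
    return len(profile.scores) == len(cds) // 3 - 1
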