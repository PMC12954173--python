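"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic under a single seed; independent named
substreams are derived from it so adding a generator never perturbs
existing draws. The generators emulate, at desk scale, the four inputs of
the study design:

* coding sequences under a **neutral** regime (codon choice within each
  synonymous family driven only by a third-position G/C target — the
  mutational-pressure null), a **selected** regime (within-family codon
  probability ∝ w^strength for an optimality table w — translational
  selection) and an **unbiased** regime (uniform within family);
* a tRNA pool with one Watson–Crick anticodon per sense codon, optionally
  co-adapted to an optimality ranking;
* per-residue disorder profiles with block-contiguous disordered segments
  and optional region-differential selection strength;
* a gene-level constraint table with a planted monotone ΔENC–O/E
  relationship calibrated to a target Spearman rho.

Amino-acid composition is uniform over the 20 amino acids by default: the
downstream analyses condition on amino-acid composition through RSCU and
ENC, so uniformity is the neutral choice. None of this mimics real gene
length distributions, isochore structure or intron architecture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import AA_TO_CODONS, DEGENERATE_AAS, STOP_CODONS
from .regions import DisorderProfile
from .adaptation import TrnaPool
from .sequence_io import TranscriptRecord, count_codons
from .usage_metrics import compute_delta_enc

#: Stop-codon draw distributions.
STOP_UNIFORM = {"TAA": 1 / 3, "TAG": 1 / 3, "TGA": 1 / 3}
#: Human-like preset: TGA-majority termination.
STOP_HUMAN_LIKE = {"TGA": 0.492, "TAA": 0.285, "TAG": 0.223}

_AAS = tuple(sorted(AA_TO_CODONS))  # fixed amino-acid order for sampling


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, name)."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


def _default_optimality() -> dict[str, float]:
    """Deterministic within-family optimality table.

    Weights fall geometrically (ratio 0.45) along a fixed codon order;
    alternate families are ranked in reverse so the optimal codons are a mix
    of G/C- and A/T-ending, keeping strong selection roughly GC3-neutral.
    """
    w: dict[str, float] = {}
    for i, aa in enumerate(_AAS):
        codons = list(AA_TO_CODONS[aa])
        if i % 2:
            codons = codons[::-1]
        for rank, c in enumerate(codons):
            w[c] = 0.45**rank
    return w


DEFAULT_OPTIMALITY: dict[str, float] = _default_optimality()


def _stop_cumprobs(stop_dist: Mapping[str, float] | None):
    dist = STOP_UNIFORM if stop_dist is None else stop_dist
    stops = list(STOP_CODONS)
    probs = np.array([dist.get(s, 0.0) for s in stops], dtype=float)
    probs = probs / probs.sum()
    return stops, np.cumsum(probs)


def _sample_body(
    probs_by_aa: Mapping[str, np.ndarray], n_codons: int, rng: np.random.Generator
) -> list[str]:
    """Draw n_codons codons: uniform amino acid, within-family per *probs*."""
    aa_idx = rng.integers(0, len(_AAS), size=n_codons)
    u = rng.random(n_codons)
    codons = [""] * n_codons
    for k, aa in enumerate(_AAS):
        positions = np.nonzero(aa_idx == k)[0]
        if positions.size == 0:
            continue
        cum = np.cumsum(probs_by_aa[aa])
        choice = np.searchsorted(cum, u[positions] * cum[-1], side="right")
        fam = AA_TO_CODONS[aa]
        for pos, ci in zip(positions, choice):
            codons[pos] = fam[min(ci, len(fam) - 1)]
    return codons


def _neutral_probs(gc3: float) -> dict[str, np.ndarray]:
    """Within-family codon probabilities hitting a third-position G/C target.

    Within each degenerate family the conditional probability of a
    G/C-ending codon is the (compensated) target, split evenly inside the
    G/C- and A/T-ending subsets. The target fed to the degenerate families
    is adjusted for the fixed G-ending contributions of Met (ATG) and Trp
    (TGG) so the realized all-sense GC3 matches the request in expectation
    under uniform amino-acid usage (targets below 0.1 therefore saturate).
    """
    t = float(np.clip((len(_AAS) * gc3 - 2.0) / len(DEGENERATE_AAS), 0.0, 1.0))
    probs: dict[str, np.ndarray] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            probs[aa] = np.array([1.0])
            continue
        gc_mask = np.array([c[2] in "GC" for c in codons])
        n_gc, n_at = int(gc_mask.sum()), int((~gc_mask).sum())
        p = np.empty(len(codons))
        if n_gc and n_at:
            p[gc_mask] = t / n_gc
            p[~gc_mask] = (1.0 - t) / n_at
        else:
            p[:] = 1.0 / len(codons)
        probs[aa] = p
    return probs


def _selected_probs(weights: Mapping[str, float], strength: float) -> dict[str, np.ndarray]:
    probs: dict[str, np.ndarray] = {}
    for aa, codons in AA_TO_CODONS.items():
        w = np.array([max(weights[c], 1e-12) for c in codons], dtype=float)
        p = np.exp(strength * np.log(w))
        probs[aa] = p / p.sum()
    return probs


def _assemble(
    body: Sequence[str],
    rng: np.random.Generator,
    stop_dist: Mapping[str, float] | None,
    transcript_id: str,
    gene_id: str | None,
) -> TranscriptRecord:
    stops, cum = _stop_cumprobs(stop_dist)
    stop = stops[int(np.searchsorted(cum, rng.random() * cum[-1], side="right").clip(0, 2))]
    cds = "ATG" + "".join(body) + stop
    return TranscriptRecord(
        transcript_id=transcript_id, gene_id=gene_id, cds=cds
    )


def generate_neutral_transcript(
    gc3: float,
    n_codons: int,
    seed: int,
    stop_dist: Mapping[str, float] | None = None,
    transcript_id: str = "ENSSYNT00000001",
    gene_id: str | None = None,
) -> TranscriptRecord:
    """A CDS whose within-family codon choice is driven only by GC3.

    *n_codons* counts protein codons including the leading ATG; a stop
    codon is appended. gc3 must lie in [0, 1]; n_codons ≥ 12.
    """
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3 must lie in [0, 1], got {gc3}")
    if n_codons < 12:
        raise ValueError("n_codons must be at least 12")
    rng = substream(seed, f"neutral:{transcript_id}")
    body = _sample_body(_neutral_probs(gc3), n_codons - 1, rng)
    return _assemble(body, rng, stop_dist, transcript_id, gene_id)


def generate_selected_transcript(
    weights,
    strength: float,
    n_codons: int,
    seed: int,
    stop_dist: Mapping[str, float] | None = None,
    transcript_id: str = "ENSSYNT00000001",
    gene_id: str | None = None,
) -> TranscriptRecord:
    """A CDS sampled with within-family probability ∝ w^strength.

    *weights* is a codon→weight mapping (or an object with a ``.w``
    attribute, e.g. CAI/tAI weights) spanning all sense codons; strength 0
    reduces to uniform-within-family.
    """
    if strength < 0:
        raise ValueError("strength must be non-negative")
    w = getattr(weights, "w", weights)
    rng = substream(seed, f"selected:{transcript_id}")
    body = _sample_body(_selected_probs(w, strength), n_codons - 1, rng)
    return _assemble(body, rng, stop_dist, transcript_id, gene_id)


def generate_trna_pool(
    seed: int = 0,
    base_copies: int = 5,
    optimality: Mapping[str, float] | None = None,
) -> TrnaPool:
    """One Watson–Crick anticodon per sense codon with positive copy numbers.

    With *optimality* given (codon → rank value), copy numbers are tied to
    the ranking — strictly increasing in rank when the ranking is strict —
    planting codon–tRNA co-adaptation. Otherwise copies are drawn from a
    seeded positive integer distribution around *base_copies*.
    """
    if base_copies < 1:
        raise ValueError("base_copies must be at least 1")
    from .genetic_code import SENSE_CODONS, revcomp

    copy_number: dict[str, int] = {}
    if optimality is not None:
        order = sorted(SENSE_CODONS, key=lambda c: optimality[c])
        for rank, codon in enumerate(order):
            copy_number[revcomp(codon)] = base_copies + rank
    else:
        rng = substream(seed, "trna_pool")
        for codon in SENSE_CODONS:
            copy_number[revcomp(codon)] = 1 + int(rng.poisson(base_copies - 1))
    return TrnaPool(copy_number=copy_number)


def generate_disordered_gene(
    idr_fraction: float,
    strength_structured: float,
    strength_idr: float,
    n_codons: int,
    seed: int,
    weights: Mapping[str, float] | None = None,
    stop_dist: Mapping[str, float] | None = None,
    transcript_id: str = "ENSSYNT00000001",
    gene_id: str | None = None,
) -> tuple[TranscriptRecord, DisorderProfile]:
    """A CDS with a contiguous disordered block and matching disorder scores.

    Residues are split into one contiguous IDR block covering
    *idr_fraction* of the protein (biological IDRs are segmental) and a
    structured remainder; codons are sampled per region with the respective
    selection strength against *weights* (default: the package optimality
    table). IDR residues get scores in [0.5, 1], structured in [0, 0.5),
    so segmentation at the standard 0.50 cutoff recovers the planted
    blocks exactly. The profile covers the protein (stop excluded), so its
    length equals *n_codons*.
    """
    if not 0.0 <= idr_fraction <= 1.0:
        raise ValueError("idr_fraction must lie in [0, 1]")
    if strength_structured < 0 or strength_idr < 0:
        raise ValueError("strengths must be non-negative")
    w = DEFAULT_OPTIMALITY if weights is None else dict(weights)
    rng = substream(seed, f"disordered:{transcript_id}")
    n_res = n_codons
    n_idr = int(round(idr_fraction * n_res))
    if n_idr > 0:
        start = int(rng.integers(1, n_res - n_idr + 2))  # 1-based block start
        idr_set = set(range(start, start + n_idr))
    else:
        idr_set = set()
    p_struct = _selected_probs(w, strength_structured)
    p_idr = _selected_probs(w, strength_idr)
    # Residue 1 is the start codon; sample residues 2..n_res run by run.
    body: list[str] = []
    run_start = 2
    runs: list[tuple[int, int, bool]] = []  # (first, last, is_idr)
    for res in range(2, n_res + 1):
        is_idr = res in idr_set
        if res == 2:
            current = is_idr
            continue
        if is_idr != current:
            runs.append((run_start, res - 1, current))
            run_start, current = res, is_idr
    if n_res >= 2:
        runs.append((run_start, n_res, current))
    for first, last, is_idr in runs:
        probs = p_idr if is_idr else p_struct
        body.extend(_sample_body(probs, last - first + 1, rng))
    record = _assemble(body, rng, stop_dist, transcript_id, gene_id)
    scores = [
        float(rng.uniform(0.5, 1.0)) if i in idr_set else float(rng.uniform(0.0, 0.5))
        for i in range(1, n_res + 1)
    ]
    profile = DisorderProfile(transcript_id=transcript_id, scores=scores)
    return record, profile


def generate_constraint_table(
    atlas: pd.DataFrame,
    target_rho: float = -0.24,
    noise: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level constraint table with a planted ΔENC–O/E Spearman rho.

    The synonymous O/E ratio is a monotone function of a latent variable
    mixing the normal scores of the ΔENC ranks with independent Gaussian
    noise of standard deviation *noise*; the mixing coefficient is
    calibrated from *target_rho* through the bivariate-normal rank
    correlation identity r = 2 sin(π ρ / 6), so the realized Spearman
    correlation concentrates on the target. ``noise = 0`` demands
    |target_rho| = 1 (the relationship is then exactly monotone); a target
    of ±1 with positive noise is unreachable. ``mu_syn`` is independent
    noise on a plausible per-site mutation-rate scale and ``syn_loeuf`` is
    co-monotone with the O/E ratio.
    """
    if atlas.empty:
        raise ValueError("atlas is empty")
    if not -1.0 <= target_rho <= 1.0:
        raise ValueError("target_rho must lie in [-1, 1]")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    valid = atlas.dropna(subset=["delta_enc"]).reset_index(drop=True)
    x = valid["delta_enc"].to_numpy(dtype=float)
    n = x.size
    sign = -1.0 if target_rho < 0 else 1.0
    t = abs(target_rho)
    rng = substream(seed, "constraints")
    ranks = sps.rankdata(x)
    zx = sps.norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom normal scores
    if noise == 0.0:
        if t != 1.0:
            raise ValueError("target_rho unreachable with noise=0 unless |rho|=1")
        latent = sign * zx
    else:
        if t >= 1.0:
            raise ValueError("|target_rho|=1 unreachable with positive noise")
        r = 2.0 * np.sin(np.pi * t / 6.0)
        a = noise * r / np.sqrt(1.0 - r**2)
        latent = sign * a * zx + noise * rng.standard_normal(n)
    syn_oe = np.exp(0.3 * (latent - latent.mean()) / (latent.std() or 1.0))
    mu_syn = np.exp(rng.normal(np.log(1.5e-8), 0.3, size=n))
    syn_loeuf = 0.1 + 1.2 * syn_oe  # co-monotone with O/E
    return pd.DataFrame(
        {
            "gene_id": valid["gene_id"].to_numpy(),
            "syn_oe": syn_oe,
            "syn_loeuf": syn_loeuf,
            "mu_syn": mu_syn,
        }
    )


@dataclass
class RegimeSpec:
    """Generation regime for one gene."""

    kind: str  # "neutral" | "selected" | "unbiased"
    gc3: float = 0.5
    strength: float = 0.0

    @property
    def expected_category(self) -> str:
        if self.kind == "selected":
            return "translational_selection"
        if self.kind == "unbiased":
            return "unbiased_control"
        if self.kind == "neutral" and self.gc3 >= 0.9:
            return "mutational_bias"
        return "intermediate"


@dataclass
class GeneratorConfig:
    """Study conditions for a full synthetic bundle.

    The default regime mix plants three well-separated populations —
    10% selected (strength 3), 10% composition-driven (neutral, GC3 0.92),
    20% unbiased (GC3 0.5) — against a 60% neutral filler with GC3 spread
    over [0.74, 0.82], sized so quantile classification at 20/80 can
    recover the planted regimes.
    """

    n_genes: int = 400
    codons_per_gene: int = 500
    regimes: Sequence[RegimeSpec] | None = None
    idr_fraction: float = 0.3
    seed: int = 0
    stop_dist: Mapping[str, float] = field(default_factory=lambda: dict(STOP_HUMAN_LIKE))

    def resolved_regimes(self) -> list[RegimeSpec]:
        if self.regimes is not None:
            if len(self.regimes) != self.n_genes:
                raise ValueError("regimes must have one entry per gene")
            return list(self.regimes)
        n = self.n_genes
        n_sel = max(1, round(0.10 * n))
        n_mut = max(1, round(0.10 * n))
        n_unb = max(1, round(0.20 * n))
        n_fill = n - n_sel - n_mut - n_unb
        fill_gc3 = np.linspace(0.74, 0.82, max(n_fill, 1))
        specs = (
            [RegimeSpec("selected", strength=3.0) for _ in range(n_sel)]
            + [RegimeSpec("neutral", gc3=0.92) for _ in range(n_mut)]
            + [RegimeSpec("unbiased", gc3=0.5) for _ in range(n_unb)]
            + [RegimeSpec("neutral", gc3=float(g)) for g in fill_gc3[:n_fill]]
        )
        return specs


def generate_gene(spec: RegimeSpec, n_codons: int, seed: int,
                  transcript_id: str, gene_id: str,
                  stop_dist: Mapping[str, float] | None = None) -> TranscriptRecord:
    """One transcript under a regime spec (shared by bundle and tests)."""
    if spec.kind == "selected":
        return generate_selected_transcript(
            DEFAULT_OPTIMALITY, spec.strength, n_codons, seed,
            stop_dist=stop_dist, transcript_id=transcript_id, gene_id=gene_id,
        )
    if spec.kind in ("neutral", "unbiased"):
        gc3 = 0.5 if spec.kind == "unbiased" else spec.gc3
        return generate_neutral_transcript(
            gc3, n_codons, seed,
            stop_dist=stop_dist, transcript_id=transcript_id, gene_id=gene_id,
        )
    raise ValueError(f"unknown regime kind: {spec.kind!r}")


def generate_atlas(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic input bundle.

    Layout: ``sequences.fa``, ``disorder/<transcript_id>.txt`` (IUPred3 long
    format), ``trna_pool.tsv`` (co-adapted to the optimality table),
    ``constraints.tsv`` and ``manifest.tsv`` (ground-truth regime per gene).
    Every CDS passes ORF QC by construction; reruns with the same config are
    byte-identical.
    """
    out = Path(out_dir)
    (out / "disorder").mkdir(parents=True, exist_ok=True)
    specs = config.resolved_regimes()
    records: list[TranscriptRecord] = []
    manifest_rows = []
    profile_rng = substream(config.seed, "profiles")
    for i, spec in enumerate(specs):
        tid = f"ENSSYNT{i + 1:08d}"
        gid = f"ENSSYNG{i + 1:08d}"
        rec = generate_gene(
            spec, config.codons_per_gene, config.seed + i, tid, gid,
            stop_dist=config.stop_dist,
        )
        records.append(rec)
        # Disorder profile: one contiguous IDR block, no codon differential.
        n_res = len(rec.cds) // 3 - 1
        n_idr = int(round(config.idr_fraction * n_res))
        start = int(profile_rng.integers(1, n_res - n_idr + 2)) if n_idr else 0
        lines = ["# POS\tRES\tIUPRED2"]
        for pos in range(1, n_res + 1):
            in_idr = n_idr and start <= pos < start + n_idr
            s = profile_rng.uniform(0.5, 1.0) if in_idr else profile_rng.uniform(0.0, 0.4999)
            lines.append(f"{pos}\tX\t{s:.4f}")
        (out / "disorder" / f"{tid}.txt").write_text("\n".join(lines) + "\n")
        manifest_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "regime": spec.kind,
                "gc3_target": spec.gc3 if spec.kind != "selected" else "",
                "strength": spec.strength if spec.kind == "selected" else "",
                "expected_category": spec.expected_category,
            }
        )
    fasta_path = out / "sequences.fa"
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}|{rec.gene_id}\n{rec.cds}\n")
    pool = generate_trna_pool(config.seed, base_copies=2, optimality=DEFAULT_OPTIMALITY)
    pool_path = out / "trna_pool.tsv"
    with open(pool_path, "w") as fh:
        fh.write("anticodon\tcopy_number\n")
        for ac in sorted(pool.copy_number):
            fh.write(f"{ac}\t{pool.copy_number[ac]}\n")
    # Constraint table planted on the realized ΔENC of the bundle itself.
    delta = [
        compute_delta_enc(count_codons(rec.cds)) for rec in records
    ]
    atlas = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "delta_enc": delta,
        }
    )
    constraints = generate_constraint_table(
        atlas, target_rho=-0.24, noise=1.0, seed=config.seed
    )
    constraints_path = out / "constraints.tsv"
    constraints.to_csv(constraints_path, sep="\t", index=False, float_format="%.6g")
    manifest_path = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    return {
        "fasta": fasta_path,
        "disorder_dir": out / "disorder",
        "trna_pool": pool_path,
        "constraints": constraints_path,
        "manifest": manifest_path,
    }
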