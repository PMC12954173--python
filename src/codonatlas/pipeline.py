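"""End-to-end atlas pipeline: read → QC → metrics → weights →
classification → regions → statistics.

CAI weights are built from the pooled counts of the QC-passing set itself
(the transcriptome-wide reference convention), then every transcript is
scored against them — the reference set is deliberately self-referential.
Outputs are TSVs with 6-significant-digit floats so reruns with identical
inputs and config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .adaptation import (
    build_cai_weights,
    build_tai_weights,
    parse_trna_pool,
)
from .classification import classify_genes, category_summary
from .regions import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_CODONS,
    extract_region_cds,
    parse_disorder_scores,
    profile_matches_cds,
    region_metrics,
    segment_regions,
)
from .sequence_io import (
    DUPLICATE_PAIR,
    TOO_SHORT_PROTEIN,
    QcReport,
    count_codons,
    parse_cds_fasta,
    pool_counts,
    qc_filter,
    translate_cds,
    write_qc_report,
)
from .stats import (
    codon_trna_correlation,
    compare_groups,
    constraint_association,
    correlate_spearman,
    read_constraint_table,
)
from .usage_metrics import (
    build_atlas_table,
    compute_rscu,
    stop_codon_usage,
    write_atlas_tsv,
)

logger = logging.getLogger(__name__)

#: Metric pairs for the Spearman inter-correlation panel.
METRIC_PAIRS = (
    ("gc3", "enc"),
    ("gc3", "delta_enc"),
    ("enc", "cai"),
    ("enc", "tai"),
    ("delta_enc", "cai"),
    ("delta_enc", "tai"),
    ("gc3", "cai"),
    ("gc3", "tai"),
)

REGION_EFFECT_METRICS = ("enc", "delta_enc", "cai", "tai", "gc3")


@dataclass
class PipelineConfig:
    cds_fasta: str
    out_dir: str
    trna_pool: str | None = None
    disorder_dir: str | None = None
    constraints: str | None = None
    constraint_columns: dict | None = None
    gc3_mode: str = "all_sense"
    enc_estimator: str = "frequency"
    q_low: float = 0.2
    q_high: float = 0.8
    disorder_cutoff: float = DEFAULT_CUTOFF
    min_region_codons: int = DEFAULT_MIN_CODONS
    min_protein_length: int = 10
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _qc_pass(config: PipelineConfig, log: dict):
    """Parse, deduplicate and QC-filter the input FASTA."""
    parse_errors: list[str] = []
    dups = []
    records = parse_cds_fasta(config.cds_fasta, errors=parse_errors, duplicates=dups)
    log["n_fasta_entries"] = len(records) + len(dups) + len(parse_errors)
    log["n_parse_errors"] = len(parse_errors)
    log["n_duplicate_pairs"] = len(dups)
    reports: list[QcReport] = []
    retained = []
    for rec in records:
        rep = qc_filter(rec)
        if rep.passed:
            _, too_short = translate_cds(rec.cds, config.min_protein_length)
            if too_short:
                rep = QcReport(rec.transcript_id, False, [TOO_SHORT_PROTEIN])
        reports.append(rep)
        if rep.passed:
            retained.append(rec)
    for rec in dups:
        reports.append(QcReport(rec.transcript_id, False, [DUPLICATE_PAIR]))
    log["n_qc_pass"] = len(retained)
    log["n_qc_fail"] = len(reports) - len(retained)
    return records, retained, reports


def _regions_pass(config: PipelineConfig, retained, cai_w, tai_w, out: Path, log: dict):
    disorder_dir = Path(config.disorder_dir)
    rows = []
    n_missing = n_mismatch = 0
    for rec in retained:
        profile_path = disorder_dir / f"{rec.transcript_id}.txt"
        if not profile_path.exists():
            n_missing += 1
            continue
        profile = parse_disorder_scores(profile_path, rec.transcript_id)
        if not profile_matches_cds(profile, rec.cds):
            logger.warning(
                "%s: disorder profile length %d != protein length %d; skipped",
                rec.transcript_id, len(profile), len(rec.cds) // 3 - 1,
            )
            n_mismatch += 1
            continue
        idr_set, structured_set = segment_regions(profile, config.disorder_cutoff)
        pair = extract_region_cds(rec.cds, idr_set, structured_set)
        if not pair.idr_cds and not pair.structured_cds:
            continue
        idr_m, str_m = region_metrics(
            pair, cai_w, tai_w,
            min_codons=config.min_region_codons,
            gc3_mode=config.gc3_mode,
            estimator=config.enc_estimator,
        )
        for region, m, cds in (
            ("idr", idr_m, pair.idr_cds),
            ("structured", str_m, pair.structured_cds),
        ):
            rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "gene_id": rec.gene_id,
                    "region": region,
                    "n_codons": len(cds) // 3,
                    "enc": m.enc_obs,
                    "gc3": m.gc3,
                    "enc_exp": m.enc_exp,
                    "delta_enc": m.delta_enc,
                    "cai": m.cai,
                    "tai": m.tai,
                }
            )
    log["n_disorder_missing"] = n_missing
    log["n_disorder_length_mismatch"] = n_mismatch
    regions_df = pd.DataFrame(rows)
    regions_df.to_csv(out / "regions.tsv", sep="\t", index=False, float_format="%.6g")
    # Cliff's Δ panel: IDR vs structured, per metric.
    effects = []
    if not regions_df.empty:
        idr = regions_df[regions_df["region"] == "idr"]
        struct = regions_df[regions_df["region"] == "structured"]
        for metric in REGION_EFFECT_METRICS:
            a = idr[metric].dropna().to_numpy(dtype=float)
            b = struct[metric].dropna().to_numpy(dtype=float)
            if a.size == 0 or b.size == 0:
                continue
            es = compare_groups(a, b)
            effects.append(
                {
                    "metric": metric,
                    "group_a": "idr",
                    "group_b": "structured",
                    "cliffs_delta": es.delta,
                    "ci_low": es.ci_low,
                    "ci_high": es.ci_high,
                    "magnitude": es.magnitude,
                    "p_wilcoxon": es.p_wilcoxon,
                    "n_a": int(a.size),
                    "n_b": int(b.size),
                }
            )
    pd.DataFrame(effects).to_csv(
        out / "region_effects.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return regions_df


def _stats_pass(config: PipelineConfig, atlas, retained, pool, out: Path, log: dict):
    corr_rows = []
    for xcol, ycol in METRIC_PAIRS:
        sub = atlas.dropna(subset=[xcol, ycol])
        if len(sub) < 3:
            continue
        res = correlate_spearman(sub[xcol], sub[ycol])
        corr_rows.append(
            {"panel": "metrics", "x": xcol, "y": ycol,
             "rho": res.rho, "p": res.p, "p_display": res.p_display, "n": res.n}
        )
    if pool is not None:
        per_gene = pd.DataFrame(
            [compute_rscu(count_codons(rec.cds)).values for rec in retained],
            index=[rec.transcript_id for rec in retained],
        )
        pooled_rscu = compute_rscu(pool_counts(count_codons(r.cds) for r in retained))
        for method in ("averaged", "pooled"):
            res = codon_trna_correlation(per_gene, pooled_rscu, pool, method=method)
            corr_rows.append(
                {"panel": f"rscu_tgcn_{method}", "x": f"rscu_{method}", "y": "tgcn",
                 "rho": res.rho, "p": res.p, "p_display": res.p_display, "n": res.n}
            )
    if config.constraints is not None:
        constraints = read_constraint_table(config.constraints, config.constraint_columns)
        assoc = constraint_association(atlas, constraints)
        for _, row in assoc.iterrows():
            corr_rows.append(
                {"panel": "constraint", "x": row["x"], "y": row["y"],
                 "rho": row["rho"], "p": row["p"],
                 "p_display": row["p_display"], "n": row["n"]}
            )
        log["n_constraint_join"] = int(assoc["n"].iloc[0])
    pd.DataFrame(corr_rows).to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )


def build_atlas(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a summary dict with output paths.

    Always emits atlas.tsv, qc_report.tsv, categories.tsv (+ thresholds),
    stop_codons.tsv and run_manifest.json under ``config.out_dir``. When a
    disorder directory is supplied, also regions.tsv and region_effects.tsv;
    when a tRNA pool and/or constraint table is supplied, correlations.tsv.
    Raises ``ValueError`` when zero transcripts pass QC.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {}

    records, retained, reports = _qc_pass(config, log)
    write_qc_report(reports, out / "qc_report.tsv")
    if not retained:
        raise ValueError("zero transcripts passed QC")

    pooled = pool_counts(count_codons(rec.cds) for rec in retained)
    cai_w = build_cai_weights(pooled)
    pool = tai_w = None
    if config.trna_pool is not None:
        pool = parse_trna_pool(config.trna_pool)
        tai_w = build_tai_weights(pool)
    else:
        logger.info("no tRNA pool supplied; tAI column left absent")

    atlas = build_atlas_table(
        retained, cai_weights=cai_w, tai_weights=tai_w,
        gc3_mode=config.gc3_mode, estimator=config.enc_estimator,
    )
    write_atlas_tsv(atlas, out / "atlas.tsv")
    log["n_atlas_rows"] = len(atlas)

    try:
        assignments, thresholds = classify_genes(atlas, config.q_low, config.q_high)
    except ValueError as exc:
        logger.warning("classification skipped: %s", exc)
        log["classification_skipped"] = str(exc)
    else:
        assignments.to_csv(out / "categories.tsv", sep="\t", index=False)
        summary = category_summary(atlas, assignments)
        summary.to_csv(
            out / "category_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(out / "thresholds.json", "w") as fh:
            json.dump(asdict(thresholds), fh, indent=1, sort_keys=True)

    stops = stop_codon_usage(retained)
    with open(out / "stop_codons.tsv", "w") as fh:
        fh.write("stop_codon\tfraction\n")
        for codon in ("TAA", "TAG", "TGA"):
            fh.write(f"{codon}\t{stops[codon]:.6g}\n")

    if config.disorder_dir is not None:
        _regions_pass(config, retained, cai_w, tai_w, out, log)
    else:
        logger.info("no disorder directory supplied; region outputs skipped")
    if pool is not None or config.constraints is not None:
        _stats_pass(config, atlas, retained, pool, out, log)
    else:
        logger.info("no pool/constraints supplied; correlations.tsv skipped")

    manifest = {
        "package_version": __version__,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict) or v
        },
        "counts": log,
        "input_digests": {
            name: _sha256(path)
            for name, path in (
                ("cds_fasta", config.cds_fasta),
                ("trna_pool", config.trna_pool),
                ("constraints", config.constraints),
            )
            if path is not None
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", log)
    return {"out_dir": out, "counts": log, "atlas": atlas}
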