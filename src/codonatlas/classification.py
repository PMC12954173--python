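"""Quantile-based stratification of genes by ENC and ΔENC.

Genes in the bottom 20th percentile of ENC carry strong overall bias; those
that simultaneously sit in the top 20th percentile of ΔENC keep that bias
after composition correction and are labelled translational-selection
genes. Low-ENC genes below the ΔENC threshold owe their bias to nucleotide
composition (mutational bias), and genes in the top 20th percentile of ENC
serve as unbiased controls. Everything else is intermediate. Threshold
comparisons are inclusive (≤ p20, ≥ p80) and quantiles are type-7
(linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TRANSLATIONAL_SELECTION = "translational_selection"
MUTATIONAL_BIAS = "mutational_bias"
UNBIASED_CONTROL = "unbiased_control"
INTERMEDIATE = "intermediate"

CATEGORIES = (
    TRANSLATIONAL_SELECTION,
    MUTATIONAL_BIAS,
    UNBIASED_CONTROL,
    INTERMEDIATE,
)


@dataclass
class QuantileThresholds:
    enc_p20: float
    enc_p80: float
    delta_enc_p80: float


@dataclass
class CategoryAssignment:
    gene_id: str
    category: str


def quantile(values: Sequence[float], q: float) -> float:
    """Type-7 (linear interpolation) sample quantile."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantile requires finite values")
    return float(np.quantile(arr, q, method="linear"))


def classify_genes(
    atlas: pd.DataFrame, q_low: float = 0.2, q_high: float = 0.8
) -> tuple[pd.DataFrame, QuantileThresholds]:
    """Assign each gene to one of the four categories.

    *atlas* needs columns ``gene_id``, ``enc`` and ``delta_enc``. Genes with
    undefined enc or delta_enc are excluded from threshold computation and
    labelled intermediate. Returns (assignments, thresholds); assignments is
    a DataFrame with columns ``gene_id`` and ``category`` covering every
    input row.
    """
    valid = atlas.dropna(subset=["enc", "delta_enc"])
    if len(valid) < 5:
        raise ValueError("need at least 5 genes with defined enc and delta_enc")
    enc = valid["enc"].to_numpy(dtype=float)
    if np.all(enc == enc[0]):
        raise ValueError("all ENC values identical: quantiles are degenerate")
    thresholds = QuantileThresholds(
        enc_p20=quantile(enc, q_low),
        enc_p80=quantile(enc, q_high),
        delta_enc_p80=quantile(valid["delta_enc"].to_numpy(dtype=float), q_high),
    )
    categories = []
    for _, row in atlas.iterrows():
        e, d = row["enc"], row["delta_enc"]
        if pd.isna(e) or pd.isna(d):
            categories.append(INTERMEDIATE)
        elif e <= thresholds.enc_p20 and d >= thresholds.delta_enc_p80:
            categories.append(TRANSLATIONAL_SELECTION)
        elif e <= thresholds.enc_p20:
            categories.append(MUTATIONAL_BIAS)
        elif e >= thresholds.enc_p80:
            categories.append(UNBIASED_CONTROL)
        else:
            categories.append(INTERMEDIATE)
    assignments = pd.DataFrame(
        {"gene_id": atlas["gene_id"].to_numpy(), "category": categories}
    )
    return assignments, thresholds


def category_summary(
    atlas: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-category n, median/mean/IQR for gc3, enc and delta_enc.

    Categories with zero members are emitted with n = 0 and absent
    statistics.
    """
    merged = atlas.merge(assignments, on="gene_id", how="left")
    rows = []
    for cat in CATEGORIES:
        sub = merged[merged["category"] == cat]
        row: dict = {"category": cat, "n": len(sub)}
        for col in ("gc3", "enc", "delta_enc"):
            vals = sub[col].dropna().to_numpy(dtype=float) if len(sub) else np.array([])
            if vals.size:
                row[f"{col}_median"] = float(np.median(vals))
                row[f"{col}_mean"] = float(np.mean(vals))
                row[f"{col}_q1"] = quantile(vals, 0.25)
                row[f"{col}_q3"] = quantile(vals, 0.75)
            else:
                row[f"{col}_median"] = row[f"{col}_mean"] = None
                row[f"{col}_q1"] = row[f"{col}_q3"] = None
        rows.append(row)
    return pd.DataFrame(rows)
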