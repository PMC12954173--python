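"""Association statistics: Spearman correlations, Cliff's Δ group
comparisons, IQR outlier filtering, codon–tRNA co-adaptation and
ΔENC-versus-constraint panels.

All codon-bias metrics are heavily non-normal, so correlations are Spearman
rank correlations and two-group comparisons pair a Wilcoxon rank-sum test
with Cliff's Δ, the probability-of-superiority effect size

    Δ = (#{a_i > b_j} − #{a_i < b_j}) / (|a|·|b|),

reported with a 95% CI from the consistent variance estimator and a
magnitude label on the |Δ| thresholds 0.147 / 0.33 / 0.474
(negligible / small / medium / large). P-values below 2.2e−16 are floored
at that sentinel, the smallest magnitude distinguishable from zero in
double precision by common statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adaptation import TrnaPool, decoding_channels, DEFAULT_S
from .genetic_code import SENSE_CODONS, revcomp
from .usage_metrics import RscuTable

P_FLOOR = 2.2e-16

NEGLIGIBLE_THRESHOLD = 0.147
SMALL_THRESHOLD = 0.33
MEDIUM_THRESHOLD = 0.474


@dataclass
class CorrelationResult:
    rho: float | None
    p: float | None
    n: int

    @property
    def p_display(self) -> str:
        if self.p is None:
            return "NA"
        if self.p <= P_FLOOR:
            return "< 2.2e-16"
        return f"{self.p:.3g}"


@dataclass
class EffectSize:
    delta: float
    ci_low: float
    ci_high: float
    magnitude: str
    p_wilcoxon: float


def _floor_p(p: float) -> float:
    return max(float(p), P_FLOOR)


def correlate_spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with an absent value on either side are dropped first; fewer than
    three remaining pairs is an error. A constant margin yields rho absent
    (None), not 0. Two-sided p via the asymptotic t approximation, floored
    at 2.2e−16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=None, p=None, n=n)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=_floor_p(p), n=n)


def cliffs_delta_magnitude(delta: float) -> str:
    # the small band is closed above so |Δ| = 0.33 is still labelled small
    a = abs(delta)
    if a < NEGLIGIBLE_THRESHOLD:
        return "negligible"
    if a <= SMALL_THRESHOLD:
        return "small"
    if a < MEDIUM_THRESHOLD:
        return "medium"
    return "large"


def compare_groups(a, b) -> EffectSize:
    """Cliff's Δ of a over b, with 95% CI and a Wilcoxon rank-sum p.

    The CI uses the consistent variance estimator of the dominance matrix
    together with the standard asymmetric transformation that keeps the
    interval inside [−1, 1]. The Wilcoxon p is exact for small untied
    samples and uses the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    d_ij = np.sign(a[:, None] - b[None, :])
    delta = float(d_ij.mean())
    di = d_ij.mean(axis=1)
    dj = d_ij.mean(axis=0)
    if n1 > 1 and n2 > 1:
        var = (
            n2**2 * np.sum((di - delta) ** 2)
            + n1**2 * np.sum((dj - delta) ** 2)
            - np.sum((d_ij - delta) ** 2)
        ) / (n1 * n2 * (n1 - 1) * (n2 - 1))
        var = max(var, 0.0)
    else:
        var = 0.0
    z = 1.959963984540054  # 97.5% normal quantile
    s2 = z**2 * var
    if var == 0.0:
        ci_low = ci_high = delta
    else:
        denom = 1 - delta**2 + s2
        half = np.sqrt(s2) * np.sqrt((1 - delta**2) ** 2 + s2)
        ci_low = float((delta - delta**3 - half) / denom)
        ci_high = float((delta - delta**3 + half) / denom)
        ci_low = max(-1.0, min(ci_low, delta))
        ci_high = min(1.0, max(ci_high, delta))
    p = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    return EffectSize(
        delta=delta,
        ci_low=ci_low,
        ci_high=ci_high,
        magnitude=cliffs_delta_magnitude(delta),
        p_wilcoxon=_floor_p(p),
    )


def iqr_filter(values, k: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 − k·IQR, Q3 + k·IQR] (type-7 quartiles)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot filter an empty list")
    q1 = np.quantile(arr, 0.25, method="linear")
    q3 = np.quantile(arr, 0.75, method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return arr[(arr >= lo) & (arr <= hi)]


def _cognate_copies(codon: str, pool: TrnaPool, wobble: bool) -> int:
    if not wobble:
        return pool.copy_number.get(revcomp(codon), 0)
    return sum(
        pool.copy_number.get(ac, 0)
        for ac, _ in decoding_channels(codon, DEFAULT_S)
    )


def codon_trna_correlation(
    per_gene_rscu: pd.DataFrame,
    pooled_rscu: RscuTable,
    pool: TrnaPool,
    method: str = "averaged",
    wobble: bool = False,
) -> CorrelationResult:
    """Spearman of per-codon RSCU against cognate tRNA gene copy number.

    ``averaged``: per codon, the per-gene RSCU values (columns of
    *per_gene_rscu*, one row per gene) are IQR-filtered and then averaged.
    ``pooled``: the single genome-wide RSCU from pooled counts is used.
    Each codon is paired with its exact Watson–Crick cognate anticodon's
    copy number (wobble-aware aggregation behind the *wobble* flag); codons
    without cognate tRNAs are dropped.
    """
    if method not in ("averaged", "pooled"):
        raise ValueError(f"unknown method: {method!r}")
    xs, ys = [], []
    for codon in SENSE_CODONS:
        copies = _cognate_copies(codon, pool, wobble)
        if copies <= 0:
            continue
        if method == "averaged":
            if codon not in per_gene_rscu.columns:
                continue
            vals = per_gene_rscu[codon].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            value = float(np.mean(iqr_filter(vals)))
        else:
            if codon not in pooled_rscu.values:
                continue
            value = pooled_rscu.values[codon]
        xs.append(value)
        ys.append(copies)
    if len(xs) < 3:
        raise ValueError("fewer than 3 codons with cognate tRNAs")
    return correlate_spearman(xs, ys)


CONSTRAINT_PAIRS = (
    ("delta_enc", "syn_oe"),
    ("delta_enc", "mu_syn"),
    ("delta_enc", "syn_loeuf"),
    ("enc", "syn_oe"),
)


def constraint_association(
    atlas: pd.DataFrame, constraints: pd.DataFrame
) -> pd.DataFrame:
    """Spearman panel of codon-bias metrics against gene-level constraint.

    Joins on ``gene_id`` (genes absent from either side are dropped and
    counted in ``n_dropped``) and correlates ΔENC with the synonymous
    observed/expected ratio, the per-site synonymous mutation rate and the
    synonymous LOEUF, plus ENC with O/E.
    """
    merged = atlas.merge(constraints, on="gene_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping gene_ids between atlas and constraints")
    n_dropped = len(atlas) + len(constraints) - 2 * len(merged)
    rows = []
    for xcol, ycol in CONSTRAINT_PAIRS:
        res = correlate_spearman(merged[xcol], merged[ycol])
        rows.append(
            {
                "x": xcol,
                "y": ycol,
                "rho": res.rho,
                "p": res.p,
                "p_display": res.p_display,
                "n": res.n,
                "n_dropped": n_dropped,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_CONSTRAINT_COLUMNS = {
    "gene_id": "gene_id",
    "syn_oe": "syn_oe",
    "syn_loeuf": "syn_loeuf",
    "mu_syn": "mu_syn",
}


def read_constraint_table(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a gene-level constraint TSV, renaming columns to the canonical
    gene_id / syn_oe / syn_loeuf / mu_syn names via *column_map* (mapping
    canonical name -> column name in the file), so gnomAD-style
    constraint-metric exports can be ingested directly.
    """
    mapping = dict(DEFAULT_CONSTRAINT_COLUMNS)
    if column_map:
        mapping.update(column_map)
    df = pd.read_csv(path, sep="\t")
    rename = {src: dst for dst, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in ("gene_id", "syn_oe") if c not in df.columns]
    if missing:
        raise ValueError(f"constraint table lacks required columns: {missing}")
    for col in ("syn_oe", "mu_syn"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in constraint column {col}")
    return df
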