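"""Spearman, Cliff's Δ, IQR filtering and the correlation panels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from codonatlas.adaptation import TrnaPool
from codonatlas.genetic_code import SENSE_CODONS, revcomp
from codonatlas.sequence_io import CodonCounts
from codonatlas.stats import (
    P_FLOOR,
    cliffs_delta_magnitude,
    codon_trna_correlation,
    compare_groups,
    constraint_association,
    correlate_spearman,
    iqr_filter,
    read_constraint_table,
)
from codonatlas.usage_metrics import compute_rscu


def cliff_oracle(a, b):
    """Exhaustive pair enumeration."""
    wins = sum(1 for x, y in itertools.product(a, b) if x > y)
    losses = sum(1 for x, y in itertools.product(a, b) if x < y)
    return (wins - losses) / (len(a) * len(b))


class TestSpearman:
    def test_monotone(self):
        assert correlate_spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)

    def test_antitone(self):
        assert correlate_spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_partial_agreement(self):
        res = correlate_spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_nan_pairs_dropped(self):
        res = correlate_spearman([1, 2, 3, np.nan], [1, 2, 3, 99])
        assert res.n == 3 and res.rho == pytest.approx(1.0)

    def test_constant_margin_gives_absent_rho(self):
        res = correlate_spearman([1, 1, 1], [1, 2, 3])
        assert res.rho is None

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            correlate_spearman([1, 2], [3, 4])

    def test_p_floored_at_sentinel(self):
        x = np.arange(2000.0)
        res = correlate_spearman(x, x + 1)
        assert res.p == P_FLOOR
        assert res.p_display == "< 2.2e-16"

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = correlate_spearman(x, y).rho
        assert correlate_spearman(np.exp(x), y).rho == pytest.approx(base)
        assert correlate_spearman(x, 3 * y + 7).rho == pytest.approx(base)


class TestCompareGroups:
    def test_complete_separation(self):
        es = compare_groups([4, 5, 6], [1, 2, 3])
        assert es.delta == 1.0
        assert es.ci_low == es.ci_high == 1.0
        assert es.magnitude == "large"

    def test_identical_groups(self):
        assert compare_groups([1, 2], [1, 2]).delta == 0.0

    def test_interleaved(self):
        assert compare_groups([1, 3], [2, 4]).delta == pytest.approx(-0.5)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_ci_brackets_delta(self, rng):
        a = rng.normal(0.5, 1, 60)
        b = rng.normal(0.0, 1, 50)
        es = compare_groups(a, b)
        assert -1 <= es.ci_low <= es.delta <= es.ci_high <= 1
        assert es.p_wilcoxon > P_FLOOR

    @pytest.mark.parametrize(
        "delta, label",
        [(0.05, "negligible"), (0.26, "small"), (0.33, "small"), (0.4, "medium"), (0.5, "large")],
    )
    def test_magnitude_labels(self, delta, label):
        assert cliffs_delta_magnitude(delta) == label

    @given(st.integers(0, 2**31 - 1))
    def test_matches_enumeration_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=int(rng.integers(1, 30))).astype(float)
        b = rng.integers(0, 10, size=int(rng.integers(1, 30))).astype(float)
        es = compare_groups(a, b)
        assert es.delta == pytest.approx(cliff_oracle(a, b))
        assert compare_groups(b, a).delta == pytest.approx(-es.delta)


class TestIqrFilter:
    def test_removes_extreme_value(self):
        assert list(iqr_filter([1, 2, 3, 4, 100])) == [1, 2, 3, 4]

    def test_constant_unchanged(self):
        assert list(iqr_filter([7, 7, 7])) == [7, 7, 7]

    def test_small_spread_unchanged(self):
        assert list(iqr_filter([1, 2, 3])) == [1, 2, 3]

    def test_idempotent_on_moderate_tails(self, rng):
        # single-pass filtering stabilizes for light-tailed samples; on very
        # heavy tails a second pass can trim further, which is expected
        vals = rng.normal(size=200)
        once = iqr_filter(vals)
        assert list(iqr_filter(once)) == list(once)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            iqr_filter([])


def _rscu_tables(rng, n_genes=30):
    """Per-gene and pooled RSCU from random counts."""
    per_gene = []
    pooled = {c: 0 for c in SENSE_CODONS}
    for _ in range(n_genes):
        counts = {c: int(rng.integers(0, 20)) for c in SENSE_CODONS}
        for c, n in counts.items():
            pooled[c] += n
        cc = CodonCounts(counts=counts, total=sum(counts.values()))
        per_gene.append(compute_rscu(cc).values)
    pooled_rscu = compute_rscu(CodonCounts(counts=pooled, total=sum(pooled.values())))
    return pd.DataFrame(per_gene), pooled_rscu


class TestCodonTrnaCorrelation:
    def test_planted_monotone_pool(self, rng):
        per_gene, pooled_rscu = _rscu_tables(rng)
        # copies = strictly increasing function of RSCU (dense rank), so
        # tied RSCU values get tied copy numbers and rho is exactly 1
        codons = list(pooled_rscu.values)
        vals = np.array([pooled_rscu.values[c] for c in codons])
        dense = np.unique(vals, return_inverse=True)[1]
        pool = TrnaPool(
            copy_number={revcomp(c): 1 + int(r) for c, r in zip(codons, dense)}
        )
        res = codon_trna_correlation(per_gene, pooled_rscu, pool, method="pooled")
        assert res.rho == pytest.approx(1.0)

    def test_permuted_pool_near_null(self, rng):
        per_gene, pooled_rscu = _rscu_tables(rng, n_genes=40)
        copies = 1 + rng.permutation(len(SENSE_CODONS))
        pool = TrnaPool(
            copy_number={revcomp(c): int(k) for c, k in zip(SENSE_CODONS, copies)}
        )
        res = codon_trna_correlation(per_gene, pooled_rscu, pool, method="averaged")
        assert abs(res.rho) < 0.35
        assert res.p > 0.01

    def test_averaged_method_robust_to_outlier_gene(self, rng):
        per_gene, pooled_rscu = _rscu_tables(rng)
        pool = TrnaPool(copy_number={revcomp(c): 2 for c in SENSE_CODONS})
        pool.copy_number[revcomp("AAA")] = 9
        base = codon_trna_correlation(per_gene, pooled_rscu, pool, method="averaged")
        spiked = per_gene.copy()
        spiked.loc[len(spiked)] = {c: 50.0 for c in spiked.columns}  # outlier gene
        res = codon_trna_correlation(spiked, pooled_rscu, pool, method="averaged")
        assert res.rho == pytest.approx(base.rho)

    def test_too_few_cognates_raises(self, rng):
        per_gene, pooled_rscu = _rscu_tables(rng)
        pool = TrnaPool(copy_number={revcomp("AAA"): 3})
        with pytest.raises(ValueError):
            codon_trna_correlation(per_gene, pooled_rscu, pool)


class TestConstraintAssociation:
    def _atlas(self, n=50):
        delta = np.linspace(0, 10, n)
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "enc": 55 - delta,
                "delta_enc": delta,
            }
        )

    def test_planted_decreasing_relationship(self):
        atlas = self._atlas()
        constraints = pd.DataFrame(
            {
                "gene_id": atlas["gene_id"],
                "syn_oe": 1.0 / (1.0 + atlas["delta_enc"]),
                "syn_loeuf": 1.0 / (1.0 + atlas["delta_enc"]),
                "mu_syn": 1e-8,
            }
        )
        table = constraint_association(atlas, constraints).set_index(["x", "y"])
        assert table.loc[("delta_enc", "syn_oe"), "rho"] == pytest.approx(-1.0)

    def test_independent_constraints_near_null(self, rng):
        atlas = self._atlas(200)
        constraints = pd.DataFrame(
            {
                "gene_id": atlas["gene_id"],
                "syn_oe": rng.random(200),
                "syn_loeuf": rng.random(200),
                "mu_syn": rng.random(200),
            }
        )
        table = constraint_association(atlas, constraints).set_index(["x", "y"])
        assert abs(table.loc[("delta_enc", "syn_oe"), "rho"]) < 0.15

    def test_disjoint_join_raises(self):
        atlas = self._atlas(5)
        constraints = pd.DataFrame(
            {"gene_id": ["X1"], "syn_oe": [1.0], "syn_loeuf": [1.0], "mu_syn": [1e-8]}
        )
        with pytest.raises(ValueError):
            constraint_association(atlas, constraints)

    def test_read_constraint_table_column_mapping(self, tmp_path):
        path = tmp_path / "constraints.tsv"
        path.write_text(
            "gene\tsyn.oe\tsyn.oe_ci.upper\tmu.syn\n"
            "ENSG1\t0.9\t1.1\t1e-8\n"
        )
        df = read_constraint_table(
            path,
            column_map={
                "gene_id": "gene",
                "syn_oe": "syn.oe",
                "syn_loeuf": "syn.oe_ci.upper",
                "mu_syn": "mu.syn",
            },
        )
        assert list(df.columns) == ["gene_id", "syn_oe", "syn_loeuf", "mu_syn"]
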