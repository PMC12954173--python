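"""RSCU, GC3, Wright's ENC, the neutral-expectation curve and ΔENC."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonatlas.genetic_code import (
    AA_TO_CODONS,
    DEGENERACY_CLASSES,
    DEGENERATE_AAS,
    SENSE_CODONS,
)
from codonatlas.sequence_io import CodonCounts, TranscriptRecord
from codonatlas.usage_metrics import (
    compute_delta_enc,
    compute_enc,
    compute_gc3,
    compute_rscu,
    expected_enc,
    stop_codon_usage,
)


def counts_from(mapping):
    return CodonCounts(counts=dict(mapping), total=sum(mapping.values()))


def enc_oracle(counts):
    """Independent symbol-by-symbol evaluation of Wright's formula
    (frequency homozygosity), kept deliberately naive."""
    class_fs = {2: [], 3: [], 4: [], 6: []}
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        n = sum(counts.counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        f = 0.0
        for c in codons:
            p = counts.counts.get(c, 0) / n
            f = f + p * p
        class_fs[len(codons)].append(f)
    if not class_fs[2] or not class_fs[4]:
        return None
    fbar = {k: sum(v) / len(v) for k, v in class_fs.items() if v}
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    if 6 not in fbar:
        fbar[6] = (fbar[2] + fbar[4]) / 2
    nc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(61.0, max(20.0, nc))


class TestRscu:
    def test_two_fold_example(self):
        r = compute_rscu(counts_from({"AAA": 3, "AAG": 1}))
        assert r.values["AAA"] == pytest.approx(1.5)
        assert r.values["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_unity(self):
        r = compute_rscu(counts_from({c: 7 for c in SENSE_CODONS}))
        assert all(v == pytest.approx(1.0) for v in r.values.values())

    def test_monopolized_family(self):
        r = compute_rscu(counts_from({"AAG": 4, "AAA": 0}))
        assert r.values["AAG"] == pytest.approx(2.0)
        assert r.values["AAA"] == 0.0

    def test_unobserved_family_absent_not_zero(self):
        r = compute_rscu(counts_from({"AAA": 1, "AAG": 1}))
        assert "GGG" not in r.values

    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_family_size(self, seed):
        rng = np.random.default_rng(seed)
        counts = counts_from(
            {c: int(rng.integers(0, 30)) for c in SENSE_CODONS}
        )
        r = compute_rscu(counts)
        for aa, codons in AA_TO_CODONS.items():
            observed = [r.values[c] for c in codons if c in r.values]
            if observed:
                assert sum(observed) == pytest.approx(len(codons))


class TestGc3:
    def test_half(self):
        assert compute_gc3(counts_from({"GAA": 1, "GAG": 1})) == pytest.approx(0.5)

    def test_complete_gc_bias(self):
        assert compute_gc3(counts_from({"GCC": 3, "GGG": 2})) == 1.0

    def test_gc3s_excludes_atg_and_tgg(self):
        counts = counts_from({"GAA": 1, "GAG": 1, "ATG": 1, "TGG": 1})
        assert compute_gc3(counts, mode="gc3s") == pytest.approx(0.5)
        # all_sense keeps ATG and TGG, both G-ending
        assert compute_gc3(counts, mode="all_sense") == pytest.approx(0.75)

    def test_stops_always_excluded(self):
        assert compute_gc3(counts_from({"GAG": 1, "TGA": 5})) == 1.0

    def test_no_included_codons_returns_none(self):
        assert compute_gc3(counts_from({"TAA": 3})) is None


class TestEnc:
    def test_single_codon_per_amino_acid_is_20(self):
        counts = counts_from({cods[0]: 5 for cods in AA_TO_CODONS.values()})
        assert compute_enc(counts).nc == pytest.approx(20.0)

    def test_uniform_usage_is_61(self):
        counts = counts_from({c: 4 for c in SENSE_CODONS})
        assert compute_enc(counts).nc == pytest.approx(61.0)

    def test_hand_evaluated_mixed_bias(self):
        # 2-folds at p=(0.75, 0.25), all other classes uniform
        counts = {}
        for aa, cods in AA_TO_CODONS.items():
            if len(cods) == 2:
                counts[cods[0]], counts[cods[1]] = 75, 25
            else:
                counts.update({c: 12 for c in cods})
        enc = compute_enc(counts_from(counts))
        assert enc.nc == pytest.approx(57.4)
        assert enc.f2bar == pytest.approx(0.625)

    def test_missing_three_fold_imputed(self):
        counts = {}
        for aa, cods in AA_TO_CODONS.items():
            if aa == "I":
                continue
            counts.update({c: 10 for c in cods})
        enc = compute_enc(counts_from(counts))
        assert enc.f3bar == pytest.approx((enc.f2bar + enc.f4bar) / 2)

    def test_undefined_without_two_fold_families(self):
        counts = counts_from({"GCT": 3, "GCC": 2})  # a lone 4-fold family
        assert compute_enc(counts) is None

    def test_wright_corrected_unbiased_on_uniform(self):
        counts = counts_from({c: 10 for c in SENSE_CODONS})
        assert compute_enc(counts, estimator="wright_corrected").nc == pytest.approx(61.0)

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        families = list(rng.choice(DEGENERATE_AAS, size=6, replace=False))
        counts = {}
        for aa in families:
            for c in AA_TO_CODONS[aa]:
                counts[c] = int(rng.integers(0, 40))
        cc = counts_from(counts)
        mine = compute_enc(cc)
        expected = enc_oracle(cc)
        if expected is None:
            assert mine is None
        else:
            assert mine.nc == pytest.approx(expected)
            assert 20.0 <= mine.nc <= 61.0


class TestExpectedEnc:
    @pytest.mark.parametrize("gc3, value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_curve_values(self, gc3, value):
        assert expected_enc(gc3) == pytest.approx(value)

    def test_maximum_at_half_and_monotone_flanks(self):
        grid = np.linspace(0, 1, 101)
        vals = [expected_enc(g) for g in grid]
        assert max(vals) == pytest.approx(expected_enc(0.5))
        left = vals[: 51]
        right = vals[50:]
        assert all(a < b for a, b in zip(left, left[1:]))
        assert all(a > b for a, b in zip(right, right[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestDeltaEnc:
    def test_extreme_bias_at_half_gc3(self):
        # one codon per amino acid, chosen so GC3 (all-sense) is exactly 0.5
        counts = {}
        for i, (aa, cods) in enumerate(sorted(AA_TO_CODONS.items())):
            gc = [c for c in cods if c[2] in "GC"]
            at = [c for c in cods if c[2] not in "GC"]
            pick = (gc or at)[0] if i % 2 else (at or gc)[0]
            counts[pick] = 5
        cc = counts_from(counts)
        gc3 = compute_gc3(cc)
        delta = compute_delta_enc(cc)
        assert compute_enc(cc).nc == pytest.approx(20.0)
        assert delta == pytest.approx(expected_enc(gc3) - 20.0)

    def test_uniform_usage_slightly_negative_at_half(self):
        counts = counts_from({c: 6 for c in SENSE_CODONS})
        gc3 = compute_gc3(counts)
        assert compute_delta_enc(counts) == pytest.approx(expected_enc(gc3) - 61.0)

    def test_undefined_when_enc_undefined(self):
        assert compute_delta_enc(counts_from({"GCT": 2})) is None


class TestStopCodonUsage:
    def test_tally(self):
        recs = [
            TranscriptRecord("T1", cds="ATGAAATGA"),
            TranscriptRecord("T2", cds="ATGAAATGA"),
            TranscriptRecord("T3", cds="ATGAAATAA"),
        ]
        usage = stop_codon_usage(recs)
        assert usage == {"TAA": pytest.approx(1 / 3), "TAG": 0.0, "TGA": pytest.approx(2 / 3)}
        assert math.isclose(sum(usage.values()), 1.0)

    def test_single_class(self):
        recs = [TranscriptRecord("T", cds="ATGAAATAA")] * 4
        assert stop_codon_usage(recs)["TAA"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            stop_codon_usage([])
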