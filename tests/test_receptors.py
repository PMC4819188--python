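"""Receptor sequence validation and PseAAC encoding on the T-scale."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bitterx.receptors import (
    AMINO_ACIDS,
    ReceptorSequence,
    SequenceValidationError,
    load_tscale,
    pseaac_feature_names,
    pseaac_features,
    read_receptor_fasta,
    tscale_correlation,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=80)


def brute_force_pseaac(seq: str, table, lam: int, w: float) -> np.ndarray:
    """Independent scalar-loop evaluation of the PseAAC formulas."""
    L = len(seq)
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            a, b = seq[i], seq[i + k]
            theta_ab = 0.0
            for t in range(5):
                d = table.row(a)[t] - table.row(b)[t]
                theta_ab += d * d
            total += theta_ab / 5.0
        thetas.append(total / (L - k))
    denom = 1.0 + w * sum(thetas)
    comp = [seq.count(aa) / L / denom for aa in AMINO_ACIDS]
    corr = [w * th / denom for th in thetas]
    return np.array(comp + corr)


class TestFasta:
    def test_single_record(self):
        recs = read_receptor_fasta(">r1\nACDE\n")
        assert len(recs) == 1
        assert recs[0].name == "r1"
        assert recs[0].length == 4

    def test_order_preserved(self):
        recs = read_receptor_fasta(">b\nAC\n>a\nDE\n")
        assert [r.name for r in recs] == ["b", "a"]

    def test_illegal_letter_names_position(self):
        with pytest.raises(SequenceValidationError, match="position 3"):
            read_receptor_fasta(">r1\nACXE\n")

    def test_whitespace_and_case_normalized(self):
        recs = read_receptor_fasta(">r\nac de\nfg\n")
        assert recs[0].residues == "ACDEFG"


class TestScaleTable:
    def test_standardized_columns(self, tscale):
        np.testing.assert_allclose(tscale.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tscale.values.std(axis=0), 1.0, atol=1e-9)

    def test_shape(self, tscale):
        assert tscale.values.shape == (20, 5)


class TestCorrelationFactors:
    def test_homopolymer_is_zero(self, tscale):
        assert tscale_correlation(ReceptorSequence("x", "AAAA"), 1, tscale) == 0.0

    def test_alternating_sequence(self, tscale):
        seq = ReceptorSequence("x", "ACAC")
        assert tscale_correlation(seq, 2, tscale) == 0.0
        # k=1 gives exactly Theta(A, C) for every adjacent pair
        theta_ac = float(np.mean((tscale.row("A") - tscale.row("C")) ** 2))
        assert tscale_correlation(seq, 1, tscale) == pytest.approx(theta_ac, abs=1e-12)

    def test_k_out_of_range(self, tscale):
        with pytest.raises(ValueError):
            tscale_correlation(ReceptorSequence("x", "ACDE"), 4, tscale)

    @given(seq=sequences, k=st.integers(1, 5))
    def test_nonnegative_and_reversal_invariant(self, seq, k):
        table = load_tscale()
        if k >= len(seq):
            return
        fwd = tscale_correlation(ReceptorSequence("f", seq), k, table)
        rev = tscale_correlation(ReceptorSequence("r", seq[::-1]), k, table)
        assert fwd >= 0.0
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestPseAAC:
    def test_homopolymer_composition_only(self, tscale):
        vec = pseaac_features(ReceptorSequence("x", "AAAAAA"), tscale, lam=2, w=0.05)
        assert vec.values[0] == pytest.approx(1.0)
        assert np.all(vec.values[1:] == 0.0)

    def test_matches_scalar_oracle(self, tscale):
        seq = "ACDEFG"
        vec = pseaac_features(ReceptorSequence("x", seq), tscale, lam=2, w=0.05)
        expected = brute_force_pseaac(seq, tscale, lam=2, w=0.05)
        np.testing.assert_allclose(vec.values, expected, atol=1e-12)

    def test_length_must_exceed_lambda(self, tscale):
        with pytest.raises(ValueError, match="lower lambda"):
            pseaac_features(ReceptorSequence("x", "ACDE"), tscale, lam=4)

    def test_order_sensitivity(self, tscale):
        a = pseaac_features(ReceptorSequence("a", "ACDACD"), tscale, lam=2, w=0.05)
        b = pseaac_features(ReceptorSequence("b", "AACDCD"), tscale, lam=2, w=0.05)
        # raw residue frequencies agree (same multiset of letters) ...
        np.testing.assert_allclose(
            a.composition / a.composition.sum(),
            b.composition / b.composition.sum(),
            atol=1e-12,
        )
        # ... but the sequence-order block separates the two orderings
        assert not np.allclose(a.correlation, b.correlation)

    def test_feature_names_align(self):
        names = pseaac_feature_names(3)
        assert len(names) == 23
        assert names[0] == "aa_A" and names[-1] == "theta_3"

    @given(seq=sequences)
    def test_sum_to_one_and_nonnegative(self, seq):
        table = load_tscale()
        lam = min(5, len(seq) - 1)
        vec = pseaac_features(ReceptorSequence("s", seq), table, lam=lam, w=0.05)
        assert vec.values.size == 20 + lam
        assert np.all(vec.values >= 0.0)
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-9)
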