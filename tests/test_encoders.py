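"""The ten descriptor families against literal-equation brute-force oracles."""

import numpy as np
import pytest

import _oracles as oracle
from bitterpep.encoders import (
    ENCODER_ORDER,
    EncoderConfig,
    EncodingLengthError,
    PeptideEncoder,
    encode_aac,
    encode_all,
    encode_apaac,
    encode_asdc,
    encode_dde,
    encode_dpc,
    encode_gaac,
    encode_gdpc,
    encode_qsorder,
    encode_socnumber,
    encode_tpaac,
)
from conftest import random_peptides

CFG = EncoderConfig()

ORACLES = {
    "AAC": lambda s: [oracle.aac_oracle(s)[r] for r in oracle.RES],
    "TPAAC": oracle.tpaac_oracle,
    "APAAC": oracle.apaac_oracle,
    "ASDC": oracle.asdc_oracle,
    "DPC": oracle.dpc_oracle,
    "DDE": oracle.dde_oracle,
    "GAAC": oracle.gaac_oracle,
    "GDPC": oracle.gdpc_oracle,
    "SOCNumber": oracle.soc_oracle,
    "QSOrder": oracle.qso_oracle,
}

ENCODERS = {
    "AAC": lambda s: encode_aac(s),
    "TPAAC": lambda s: encode_tpaac(s, CFG),
    "APAAC": lambda s: encode_apaac(s, CFG),
    "ASDC": lambda s: encode_asdc(s),
    "DPC": lambda s: encode_dpc(s),
    "DDE": lambda s: encode_dde(s),
    "GAAC": lambda s: encode_gaac(s),
    "GDPC": lambda s: encode_gdpc(s),
    "SOCNumber": lambda s: encode_socnumber(s, CFG),
    "QSOrder": lambda s: encode_qsorder(s, CFG),
}

EXPECTED_DIMS = dict(zip(ENCODER_ORDER, (20, 21, 22, 400, 400, 400, 5, 25, 2, 42)))


@pytest.mark.parametrize("name", ENCODER_ORDER)
def test_encoder_matches_brute_force_oracle(name, seeded_peptides):
    """Each encoder agrees with its independent loop-based oracle to 1e-10
    per component on 200 seeded random peptides of lengths 2-30."""
    enc, orc = ENCODERS[name], ORACLES[name]
    for seq in seeded_peptides:
        got = enc(seq).values
        expected = np.array(orc(seq), dtype=float)
        np.testing.assert_allclose(got, expected, atol=1e-10, rtol=0,
                                   err_msg=f"{name} on {seq}")


@pytest.mark.parametrize("name", ENCODER_ORDER)
def test_default_dimensions(name):
    vec = ENCODERS[name]("GFLK")
    assert len(vec) == EXPECTED_DIMS[name]
    assert len(vec.names) == len(set(vec.names))


def test_total_fused_dimension_is_1337():
    vecs = encode_all("GF")
    assert [v.encoder for v in vecs] == list(ENCODER_ORDER)
    assert sum(len(v) for v in vecs) == 1337


def test_dipeptide_encodable_by_all_ten_at_defaults():
    for v in encode_all("GF"):
        assert np.isfinite(v.values).all()


class TestNormalizationInvariants:
    """Composition-style encoders sum to one; QSOrder per matrix block."""

    def test_sums_on_1000_random_peptides(self):
        rng = np.random.default_rng(42)
        peptides = random_peptides(1000, rng, 2, 30)
        for seq in peptides:
            for name in ("AAC", "TPAAC", "APAAC", "ASDC", "DPC", "GAAC", "GDPC"):
                total = ENCODERS[name](seq).values.sum()
                assert total == pytest.approx(1.0, abs=1e-9), (name, seq)
            q = encode_qsorder(seq, CFG).values
            block = 20 + CFG.nlag
            assert q[:block].sum() == pytest.approx(1.0, abs=1e-9)
            assert q[block:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_outputs_finite_on_long_random_peptides(self):
        rng = np.random.default_rng(7)
        for seq in random_peptides(100, rng, 2, 50):
            for v in encode_all(seq):
                assert np.isfinite(v.values).all()


class TestTrivialCases:
    def test_aac_direct_count(self):
        v = encode_aac("AAY")
        byname = dict(zip(v.names, v.values))
        assert byname["A"] == pytest.approx(2 / 3)
        assert byname["Y"] == pytest.approx(1 / 3)
        assert sum(byname.values()) == pytest.approx(1.0)

    def test_tpaac_homopolymer_theta_vanishes(self):
        v = encode_tpaac("AAAA", CFG)
        byname = dict(zip(v.names, v.values))
        assert byname["A"] == pytest.approx(1.0)
        assert byname["lambda1"] == pytest.approx(0.0)

    def test_asdc_exhaustive_pairs(self):
        v = encode_asdc("AAA")
        byname = dict(zip(v.names, v.values))
        assert byname["AA"] == pytest.approx(1.0)
        v = encode_asdc("AY")
        byname = dict(zip(v.names, v.values))
        assert byname["AY"] == pytest.approx(1.0)

    def test_dpc_direct_count(self):
        byname = dict(zip(*(lambda v: (v.names, v.values))(encode_dpc("ARA"))))
        assert byname["AR"] == pytest.approx(0.5)
        assert byname["RA"] == pytest.approx(0.5)

    def test_dde_absent_dipeptides_strictly_negative(self):
        v = encode_dde("AA")
        byname = dict(zip(v.names, v.values))
        for pair, val in byname.items():
            if pair == "AA":
                assert val > 0
            else:
                assert val < 0

    def test_dde_aa_literal_value(self):
        tm = (4 / 61) ** 2
        tv = tm * (1 - tm) / 1
        expected = (1 - tm) / np.sqrt(tv)
        v = encode_dde("AA")
        assert dict(zip(v.names, v.values))["AA"] == pytest.approx(expected)

    def test_gaac_one_residue_per_group(self):
        v = encode_gaac("GFKDS")
        np.testing.assert_allclose(v.values, 0.2)
        v = encode_gaac("GGGG")
        assert dict(zip(v.names, v.values))["g1"] == 1.0

    def test_gdpc_single_pair(self):
        v = encode_gdpc("GF")
        byname = dict(zip(v.names, v.values))
        assert byname["g1.g2"] == 1.0
        assert sum(byname.values()) == pytest.approx(1.0)

    def test_socnumber_homopolymer_zero(self):
        np.testing.assert_allclose(encode_socnumber("AAAA", CFG).values, 0.0)

    def test_qsorder_homopolymer_reduces_to_composition(self):
        v = encode_qsorder("AAAA", CFG)
        byname = dict(zip(v.names, v.values))
        assert byname["SchneiderWrede.A"] == pytest.approx(1.0)
        assert byname["SchneiderWrede.lag1"] == pytest.approx(0.0)
        assert byname["Grantham.A"] == pytest.approx(1.0)
        assert byname["Grantham.lag1"] == pytest.approx(0.0)


class TestPermutationBehaviour:
    def test_aac_gaac_permutation_invariant(self):
        rng = np.random.default_rng(3)
        for seq in random_peptides(20, rng, 4, 15):
            shuffled = "".join(rng.permutation(list(seq)))
            np.testing.assert_allclose(
                encode_aac(seq).values, encode_aac(shuffled).values
            )
            np.testing.assert_allclose(
                encode_gaac(seq).values, encode_gaac(shuffled).values
            )

    def test_order_sensitive_encoders_have_witness(self):
        # a permutation that changes the adjacent-pair multiset (a plain
        # reversal would not move SOCNumber, whose matrices are symmetric)
        a, b = "ARNDK", "ANRDK"
        assert not np.allclose(encode_dpc(a).values, encode_dpc(b).values)
        assert not np.allclose(encode_asdc(a).values, encode_asdc(b).values)
        assert not np.allclose(
            encode_socnumber(a, CFG).values, encode_socnumber(b, CFG).values
        )

    def test_homopolymer_length_scaling_leaves_compositions_unchanged(self):
        np.testing.assert_allclose(
            encode_aac("CCC").values, encode_aac("CCCCCC").values
        )
        np.testing.assert_allclose(
            encode_gaac("CCC").values, encode_gaac("CCCCCC").values
        )


class TestLengthErrors:
    def test_lambda_too_large(self):
        cfg = EncoderConfig(lambda_=3)
        with pytest.raises(EncodingLengthError):
            encode_tpaac("GFL", cfg)
        with pytest.raises(EncodingLengthError):
            encode_apaac("GFL", cfg)

    def test_nlag_too_large(self):
        cfg = EncoderConfig(nlag=5)
        with pytest.raises(EncodingLengthError):
            encode_socnumber("GFLK", cfg)
        with pytest.raises(EncodingLengthError):
            encode_qsorder("GFLK", cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(lambda_=0)
        with pytest.raises(ValueError):
            EncoderConfig(w_apaac=-1.0)


class TestLargerLags:
    """λ and nlag are configurable; oracles cover the non-default settings."""

    @pytest.mark.parametrize("lam", [2, 3])
    def test_tpaac_apaac_at_higher_lambda(self, lam):
        cfg = EncoderConfig(lambda_=lam)
        rng = np.random.default_rng(lam)
        for seq in random_peptides(20, rng, lam + 1, 20):
            np.testing.assert_allclose(
                encode_tpaac(seq, cfg).values,
                oracle.tpaac_oracle(seq, lam=lam), atol=1e-10,
            )
            np.testing.assert_allclose(
                encode_apaac(seq, cfg).values,
                oracle.apaac_oracle(seq, lam=lam), atol=1e-10,
            )
            assert len(encode_tpaac(seq, cfg)) == 20 + lam
            assert len(encode_apaac(seq, cfg)) == 20 + 2 * lam

    def test_soc_qso_at_higher_nlag(self):
        cfg = EncoderConfig(nlag=3)
        rng = np.random.default_rng(11)
        for seq in random_peptides(20, rng, 4, 20):
            np.testing.assert_allclose(
                encode_socnumber(seq, cfg).values,
                oracle.soc_oracle(seq, nlag=3), atol=1e-8,
            )
            np.testing.assert_allclose(
                encode_qsorder(seq, cfg).values,
                oracle.qso_oracle(seq, nlag=3), atol=1e-10,
            )


def test_custom_property_set_generalizes_theta():
    """TPAAC's correlation accepts an arbitrary normalized property set;
    with only the hydrophobicity/hydrophilicity pair, theta is the two-term
    mean square difference."""
    from bitterpep.properties import default_scales

    two = default_scales()[:2]
    cfg = EncoderConfig(scales=two)
    seq = "GFLK"
    got = encode_tpaac(seq, cfg).values
    h1, h2 = (s.as_dict() for s in two)
    theta = sum(
        ((h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2) / 2
        for a, b in zip(seq, seq[1:])
    ) / (len(seq) - 1)
    freqs = [seq.count(r) / len(seq) for r in oracle.RES]
    denom = 1 + 0.05 * theta
    expected = [f / denom for f in freqs] + [0.05 * theta / denom]
    np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPeptideEncoderTransformer:
    def test_feature_names_are_qualified_and_stable(self):
        enc = PeptideEncoder().fit()
        names = enc.get_feature_names_out()
        assert len(names) == 1337
        assert names[0] == "AAC.A"
        assert names[20] == "TPAAC.A"
        assert names[-1] == "QSOrder.Grantham.lag1"
        assert len(set(names)) == 1337

    def test_transform_matches_encode_all(self, seeded_peptides):
        enc = PeptideEncoder().fit()
        sample = seeded_peptides[:10]
        mat = enc.transform(sample)
        for row, seq in zip(mat, sample):
            expected = np.concatenate([v.values for v in encode_all(seq)])
            np.testing.assert_allclose(row, expected)

    def test_encoder_subset_and_sklearn_params(self):
        enc = PeptideEncoder(encoders=("DPC", "AAC")).fit()
        assert enc.n_features_out_ == 420
        # canonical order regardless of requested order
        assert enc.feature_names_out_[0] == "AAC.A"
        assert enc.get_params()["nlag"] == 1
        enc2 = enc.set_params(nlag=2).fit()
        assert enc2.n_features_out_ == 420  # nlag only affects SOC/QSOrder

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PeptideEncoder(encoders=("AAC", "NOPE")).fit()
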