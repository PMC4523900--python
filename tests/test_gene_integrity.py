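"""GIS scores, Fisher transform, transcript features, binning and regression."""

import re

import numpy as np
import pandas as pd
import pytest

from mrin.gene_integrity import (
    DEFAULT_GROUPS,
    FeatureError,
    bin_correlate,
    compute_gis,
    count_motif,
    extract_features,
    features_table,
    fisher_transform,
    ranked_gene_lists,
    regress_gis,
)
from mrin.gene_models import GeneModel
from conftest import make_transcript


def _quality(n, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    return pd.Series(rng.normal(0, 0.05, n), index=[f"s{i}" for i in range(n)])


class TestComputeGIS:
    def test_perfect_anticorrelation(self):
        q = _quality(12)
        mks = pd.DataFrame([-q.to_numpy()], index=["g"], columns=q.index)
        out = compute_gis(mks, q)
        assert out.loc["g", "gis"] == pytest.approx(-1.0, abs=1e-12)

    def test_three_point_toy(self):
        q = pd.Series([-0.2, 0.0, 0.2], index=["a", "b", "c"])
        mks = pd.DataFrame([[0.1, 0.0, -0.1]], index=["g"], columns=q.index)
        out = compute_gis(mks, q, min_samples=3)
        assert out.loc["g", "gis"] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_gene_is_near_zero(self):
        rng = np.random.default_rng(31)
        q = _quality(300, rng)
        mks = pd.DataFrame([rng.normal(0, 0.01, 300)], index=["g"], columns=q.index)
        out = compute_gis(mks, q)
        assert abs(out.loc["g", "gis"]) < 0.12

    def test_invariant_under_positive_affine_quality_rescale(self):
        rng = np.random.default_rng(7)
        q = _quality(40, rng)
        mks = pd.DataFrame(rng.normal(0, 0.02, (5, 40)),
                           index=[f"g{i}" for i in range(5)], columns=q.index)
        a = compute_gis(mks, q)["gis"]
        b = compute_gis(mks, 3.5 * q + 7.0)["gis"]
        assert np.allclose(a, b, atol=1e-12)

    def test_min_samples_and_zero_variance_reasons(self):
        q = _quality(12)
        mks = pd.DataFrame(
            {
                "few": [0.1] * 5 + [np.nan] * 7,
                "flat": [0.2] * 12,
            },
            index=q.index,
        ).T
        out = compute_gis(mks, q)
        assert out.loc["few", "reason"] == "too_few_samples"
        assert out.loc["flat", "reason"] == "zero_variance"
        assert out["gis"].isna().all()

    def test_uses_only_jointly_observed_samples(self):
        q = pd.Series(np.arange(12, dtype=float), index=[f"s{i}" for i in range(12)])
        row = -q.to_numpy()
        row[3] = np.nan
        mks = pd.DataFrame([row], index=["g"], columns=q.index)
        out = compute_gis(mks, q)
        assert out.loc["g", "n_samples_used"] == 11
        assert out.loc["g", "gis"] == pytest.approx(-1.0, abs=1e-12)


class TestFisherTransform:
    def test_values(self):
        assert fisher_transform(0.0) == 0.0
        assert fisher_transform(0.5) == pytest.approx(np.log(3) / 2)

    def test_antisymmetry(self):
        for g in (0.1, 0.37, 0.9):
            assert fisher_transform(-g) == pytest.approx(-fisher_transform(g))

    def test_clipping_at_one_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            v = fisher_transform(1.0)
        assert v == pytest.approx(np.arctanh(1 - 1e-6))

    def test_inverse_roundtrip(self):
        g = np.linspace(-0.999, 0.999, 101)
        back = np.tanh(np.arctanh(g))
        assert np.allclose(back, g, atol=1e-12)


class TestMotifCounting:
    def test_overlapping_are_matches(self):
        assert count_motif("AUUUAUUUA", "AUUUA") == 2

    def test_pum2_consensus_instantiation(self):
        assert count_motif("UGUAAAUA", "UGUAHAUA") == 1
        assert count_motif("UGUAGAUA", "UGUAHAUA") == 0  # H excludes G

    def test_dna_input_is_transcribed(self):
        assert count_motif("ATTTATTTA", "AUUUA") == 2

    def test_agrees_with_regex_oracle(self):
        rng = np.random.default_rng(41)
        alphabet = np.array(list("ACGU"))
        are_re = re.compile("(?=AUUUA)")
        pum2_re = re.compile("(?=UGUA[ACU]AUA)")
        for _ in range(1000):
            seq = "".join(rng.choice(alphabet, size=rng.integers(8, 120)))
            assert count_motif(seq, "AUUUA") == len(are_re.findall(seq))
            assert count_motif(seq, "UGUAHAUA") == len(pum2_re.findall(seq))


def _coding_tx(strand="+", utr5="GGGCCC", cds="AUGAAAUUUUAA",
               utr3="AUUUAUUUAUAG"):
    """Single-exon coding transcript with the given region sequences."""
    seq5to3 = utr5 + cds + utr3
    L = len(seq5to3)
    if strand == "+":
        cds_g = (len(utr5), len(utr5) + len(cds))
    else:
        cds_g = (len(utr3), len(utr3) + len(cds))
    tx = make_transcript(strand=strand, exons=((0, L),), cds=cds_g)
    return tx, seq5to3


class TestExtractFeatures:
    def test_region_lengths_gc_and_motifs(self):
        tx, seq = _coding_tx()
        f = extract_features(tx, seq)
        assert (f.len_5utr, f.len_cds, f.len_3utr) == (6, 12, 12)
        assert f.len_tx == 30
        assert f.gc_5utr == 1.0
        assert f.gc_3utr == pytest.approx(1 / 12)
        assert f.are_count == 2  # overlapping AUUUA at offsets 0 and 4
        assert f.are_density == pytest.approx(2 / 0.012)

    def test_minus_strand_equivalent(self):
        f_plus = extract_features(*_coding_tx("+"))
        f_minus = extract_features(*_coding_tx("-"))
        for attr in ("len_5utr", "len_cds", "len_3utr", "gc_5utr", "gc_3utr",
                     "are_count", "pum2_count"):
            assert getattr(f_plus, attr) == getattr(f_minus, attr)

    def test_dna_alphabet_accepted(self):
        tx, seq = _coding_tx()
        f = extract_features(tx, seq.replace("U", "T"))
        assert f.are_count == 2

    def test_cds_not_multiple_of_three_excluded(self):
        tx, seq = _coding_tx(cds="AUGAAAUUUUA")  # 11 nt
        with pytest.raises(FeatureError, match="multiple of 3"):
            extract_features(tx, seq)

    def test_missing_utr_excluded(self):
        tx, seq = _coding_tx(utr5="")
        with pytest.raises(FeatureError, match="UTR"):
            extract_features(tx, seq)

    def test_noncoding_excluded(self):
        tx = make_transcript(exons=((0, 30),))
        with pytest.raises(FeatureError, match="non-coding"):
            extract_features(tx, "A" * 30)

    def test_sequence_length_mismatch(self):
        tx, seq = _coding_tx()
        with pytest.raises(FeatureError, match="length"):
            extract_features(tx, seq + "A")

    def test_features_table_collects_and_skips(self):
        good_tx, good_seq = _coding_tx()
        bad_tx = make_transcript(tx_id="TXnc", gene_id="Gnc", exons=((0, 10),))
        genes = [
            GeneModel("G1", good_tx),
            GeneModel("Gnc", bad_tx),
        ]
        seqs = {"TX1": good_seq, "TXnc": "A" * 10}
        feats, skipped = features_table(genes, seqs)
        assert list(feats.index) == ["G1"]
        assert skipped.loc[0, "gene_id"] == "Gnc"


def _random_features(n, seed=0):
    rng = np.random.default_rng(seed)
    len_3utr = rng.integers(100, 3000, n)
    feats = pd.DataFrame(
        {
            "len_tx": rng.integers(500, 10000, n),
            "len_5utr": rng.integers(50, 500, n),
            "len_cds": 3 * rng.integers(100, 2000, n),
            "len_3utr": len_3utr,
            "n_exons": rng.integers(1, 30, n),
            "gc_5utr": rng.uniform(0.3, 0.8, n),
            "gc_cds": rng.uniform(0.3, 0.7, n),
            "gc_3utr": rng.uniform(0.2, 0.6, n),
            "are_density": rng.uniform(0, 5, n),
            "pum2_density": rng.uniform(0, 1, n),
        },
        index=[f"g{i}" for i in range(n)],
    )
    return feats, rng


class TestBinCorrelate:
    def test_complete_bins_by_floor_division(self):
        feats, rng = _random_features(350)
        gis = pd.Series(rng.normal(0, 0.1, 350), index=feats.index)
        out = bin_correlate(feats, gis, bin_size=100, order_by="len_tx")
        assert set(out.index) == set(feats.columns)

    def test_fewer_than_three_bins_is_an_error(self):
        feats, rng = _random_features(250)
        gis = pd.Series(rng.normal(0, 0.1, 250), index=feats.index)
        with pytest.raises(ValueError, match="bins"):
            bin_correlate(feats, gis, bin_size=100)

    def test_constant_feature_reported_missing(self):
        feats, rng = _random_features(400)
        feats["gc_cds"] = 0.5
        gis = pd.Series(rng.normal(0, 0.1, 400), index=feats.index)
        out = bin_correlate(feats, gis, bin_size=100)
        assert np.isnan(out["gc_cds"])

    def test_constructed_linear_relation_is_recovered(self):
        feats, rng = _random_features(1200, seed=3)
        gis = pd.Series(
            -0.0001 * feats["len_tx"] + rng.normal(0, 0.02, 1200),
            index=feats.index,
        )
        out = bin_correlate(feats, gis, bin_size=100, order_by="len_tx")
        assert out["len_tx"] < -0.9


class TestRegressGIS:
    def test_noiseless_linear_response_r2_is_one(self):
        feats, _ = _random_features(500, seed=5)
        y = 0.3 - 0.2 * np.log(feats["len_tx"] + 1.0)
        out = regress_gis(feats, y)
        assert out["lengths"]["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert out["lengths"]["coefficients"]["log_len_tx"] == pytest.approx(-0.2)

    def test_independent_response_r2_near_zero(self):
        feats, rng = _random_features(5000, seed=9)
        y = pd.Series(rng.normal(0, 0.3, 5000), index=feats.index)
        out = regress_gis(feats, y)
        assert out["combined"]["r_squared"] < 0.01

    def test_planted_effect_recovered(self):
        feats, rng = _random_features(5000, seed=13)
        x = np.log(feats["len_tx"] + 1.0)
        target_r2 = 0.15
        noise_sd = float(x.std(ddof=0)) * np.sqrt((1 - target_r2) / target_r2)
        y = -x + rng.normal(0, noise_sd, 5000)
        out = regress_gis(feats, y)
        assert out["lengths"]["r_squared"] == pytest.approx(target_r2, abs=0.03)
        assert out["combined"]["r_squared"] >= out["lengths"]["r_squared"]

    def test_collinear_column_dropped_with_warning(self):
        feats, rng = _random_features(300, seed=15)
        feats["pum2_density"] = 2.0 * feats["are_density"]  # exact collinearity
        y = pd.Series(rng.normal(0, 0.1, 300), index=feats.index)
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_gis(feats, y)
        assert "pum2_density" not in out["regulatory"]["coefficients"]

    def test_default_groups_cover_the_three_variable_sets(self):
        assert set(DEFAULT_GROUPS) == {"lengths", "base_composition", "regulatory"}


class TestRankedLists:
    def test_top_and_bottom(self):
        gis = pd.DataFrame({"gis": np.linspace(-0.9, 0.9, 50)},
                           index=[f"g{i}" for i in range(50)])
        lists = ranked_gene_lists(gis, n=5)
        assert lists["most_unstable"] == [f"g{i}" for i in range(5)]
        assert lists["most_stable"][0] == "g49"
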