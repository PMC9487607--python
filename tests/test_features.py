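"""Feature extractors, QuiPT, LZ76 similarity and PCA."""

import itertools
import math

import numpy as np
import pytest

from ampbench import features as F
from ampbench import scales
from ampbench.seqdata import AMINO_ACIDS

PEP = "KWKLFKKIEKVG"  # a 12-mer used in several hand computations


class TestDimensions:
    @pytest.mark.parametrize("fn,expected", [
        (lambda s: F.aac(s), 20),
        (lambda s: F.pseaac(s, lam=20, clip_lam=True), 40),
        (lambda s: F.ctd_distribution(s), 105),
        (lambda s: F.ampep_subset(s), 23),
        (lambda s: F.cs_amppred_features(s), 9),
        (lambda s: F.ampir_features(s), 27),
        (lambda s: F.macrel_features(s), 22),
        (lambda s: F.mlamp_features(s), 30),
    ])
    def test_published_feature_space_sizes(self, fn, expected):
        fv = fn("ACDEFGHIKLMNPQRSTVWYKKLL")
        assert len(fv) == expected
        assert np.all(np.isfinite(fv.values))


class TestAac:
    def test_simple_counts(self):
        fv = F.aac("ACDE")
        by_name = dict(zip(fv.names, fv.values))
        for aa in "ACDE":
            assert by_name[f"aac_{aa}"] == 0.25
        assert fv.values.sum() == pytest.approx(1.0)

    def test_homopolymer(self):
        fv = F.aac("AAAA")
        assert fv.values[0] == 1.0 and fv.values[1:].sum() == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            F.aac("")

    def test_permutation_invariant(self, rng):
        s = "KWKLFKKIEKVG"
        perm = "".join(rng.permutation(list(s)))
        assert np.allclose(F.aac(s).values, F.aac(perm).values)


class TestPseaac:
    def test_homopolymer_reduces_to_pure_aac(self):
        fv = F.pseaac("A" * 30, lam=5)
        assert fv.values[0] == pytest.approx(1.0)
        assert np.allclose(fv.values[1:], 0.0)

    def test_length_contract_error(self):
        with pytest.raises(ValueError):
            F.pseaac("KWKL", lam=20)

    def test_clip_lam_keeps_dimension(self):
        fv = F.pseaac("KWKLF", lam=20, clip_lam=True)
        assert len(fv) == 40
        assert np.allclose(fv.values[20 + 4:], 0.0)  # no pairs beyond L-1

    def test_matches_step_by_step_hand_computation(self):
        # independent re-derivation of Chou's definition for lam=2, one scale
        lam, w = 2, 0.05
        scale = scales.EISENBERG
        vals = np.array([scale[a] for a in AMINO_ACIDS])
        std = {a: (scale[a] - vals.mean()) / vals.std() for a in AMINO_ACIDS}
        seq = PEP
        thetas = []
        for j in (1, 2):
            diffs = [(std[seq[i + j]] - std[seq[i]]) ** 2
                     for i in range(len(seq) - j)]
            thetas.append(sum(diffs) / len(diffs))
        freqs = [seq.count(a) / len(seq) for a in AMINO_ACIDS]
        denom = 1 + w * sum(thetas)
        expected = np.array(freqs + [w * t for t in thetas]) / denom
        fv = F.pseaac(seq, lam=2, weight=w, property_scales=(scale,))
        assert np.allclose(fv.values, expected, atol=1e-12)

    def test_order_sensitive(self):
        # same residue multiset, non-reversal rearrangement (the theta
        # factors are invariant under exact reversal, so a reversal would
        # not witness order sensitivity)
        a = F.pseaac("KWKLFKKIEKVG", lam=2)
        b = F.pseaac("KKKKKWLFIEVG", lam=2)
        assert np.allclose(F.aac("KWKLFKKIEKVG").values,
                           F.aac("KKKKKWLFIEVG").values)
        assert not np.allclose(a.values, b.values)


class TestCtdDistribution:
    def test_homopolymer_closed_form(self):
        L = 10
        fv = F.ctd_distribution("A" * L)
        expected_present = [1 / L, math.ceil(0.25 * L) / L,
                            math.ceil(0.5 * L) / L,
                            math.ceil(0.75 * L) / L, 1.0]
        for attr, groups in scales.CTD_ATTRIBUTES:
            for ci, group in enumerate(groups, start=1):
                idx = [i for i, n in enumerate(fv.names)
                       if n.startswith(f"{attr}_c{ci}_")]
                block = fv.values[idx]
                if "A" in group:
                    assert np.allclose(block, expected_present)
                else:
                    assert np.allclose(block, 0.0)

    def test_order_sensitive_unlike_aac(self):
        s, perm = "KWKLFKKIEKVG", "GVKEIKKFLKWK"
        assert not np.allclose(F.ctd_distribution(s).values,
                               F.ctd_distribution(perm).values)
        assert np.allclose(F.aac(s).values, F.aac(perm).values)

    def test_absent_class_gives_zeros_not_nan(self):
        fv = F.ctd_distribution("KKKK")  # many classes absent
        assert np.all(np.isfinite(fv.values))


class TestAmpepSubset:
    def test_projection_of_full_ctd(self):
        full = F.ctd_distribution(PEP)
        sub = F.ampep_subset(PEP)
        for i, j in enumerate(F.AMPEP_SUBSET_INDICES):
            assert sub.values[i] == full.values[j]
            assert sub.names[i] == full.names[j]


class TestPhyschem:
    def test_charge_signs(self):
        assert F.net_charge("K", 7.0) > 0
        assert F.net_charge("D", 7.0) < 0

    def test_pi_is_charge_root(self):
        for pep in ("KWKLFKKIEK", "DDEE", "ACDKRH"):
            pi = F.isoelectric_point(pep)
            assert abs(F.net_charge(pep, pi)) < 1e-6

    def test_homopolymer_moment_vanishes(self):
        # 18 residues x 100 deg = 5 full turns: vectors cancel exactly
        assert F.hydrophobic_moment("L" * 18) < 1e-10
        amphipathic = F.hydrophobic_moment("LKKLLKLLKKLLKLLKKL")
        assert F.hydrophobic_moment("L" * 18) < amphipathic

    def test_panel_keys_and_finiteness(self):
        panel = F.physchem_panel(PEP)
        expected = {"net_charge", "isoelectric_point", "hydrophobicity_mean",
                    "hydrophobic_moment", "instability_index",
                    "aliphatic_index", "boman_index", "amphipathicity",
                    "flexibility", "alpha_propensity", "beta_propensity",
                    "loop_propensity", "molecular_weight", "solubility_flag"}
        assert set(panel) == expected
        assert all(np.isfinite(v) for v in panel.values())


class TestProjectionFeatures:
    def test_cs_amppred_entries_come_from_panel(self):
        fv = F.cs_amppred_features(PEP)
        panel = F.physchem_panel(PEP)
        by_name = dict(zip(fv.names, fv.values))
        for key in ("net_charge", "hydrophobicity_mean", "flexibility",
                    "amphipathicity", "hydrophobic_moment"):
            assert by_name[key] == panel[key]

    def test_cs_amppred_pure_function(self):
        assert np.allclose(F.cs_amppred_features(PEP).values,
                           F.cs_amppred_features(PEP).values)

    def test_ampir_concatenation(self):
        fv = F.ampir_features(PEP)
        pse = F.pseaac(PEP, lam=2)
        panel = F.physchem_panel(PEP)
        assert np.allclose(fv.values[:22], pse.values)
        assert fv.values[22] == panel["amphipathicity"]
        assert fv.values[26] == panel["net_charge"]

    def test_macrel_first_occurrence_closed_form(self):
        # homopolymer: 1/L for its own group, 0 for the others
        L = 8
        fv = F.macrel_features("I" * L)
        by_name = dict(zip(fv.names, fv.values))
        assert by_name["fet_g1_first"] == pytest.approx(1 / L)  # I in group 1
        assert by_name["fet_g2_first"] == 0.0
        assert by_name["fet_g3_first"] == 0.0
        assert by_name["fet_g1_fraction"] == 1.0


class TestMlamp:
    def test_constant_series_gives_zero_development_coefficient(self):
        a, b = F.gm11_coefficients([1.5] * 10)
        assert abs(a) < 1e-9
        assert b == pytest.approx(1.5)

    def test_homopolymer_grey_coefficients(self):
        fv = F.mlamp_features("A" * 12)
        by_name = dict(zip(fv.names, fv.values))
        for scale in ("eisenberg_hydrophobicity", "side_chain_mass"):
            assert abs(by_name[f"gm_a_{scale}"]) < 1e-9

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            F.mlamp_features("KWK")


class TestNgrams:
    def test_kwk_enumeration(self):
        grams = set(F._seq_ngrams("KWK"))
        assert grams == {"K", "W", "KW", "WK", "KWK", "K_K"}

    def test_zero_vector_for_unseen_peptide(self):
        vocab = F.build_ngram_vocabulary(["KWK"])
        row = F.ngram_features("DDDD", vocab)
        assert row.nnz == 0

    def test_matrix_rows_match_single_extraction(self, rng):
        seqs = ["KWKLFKKI", "GGDDEEKK", "AAAA"]
        vocab = F.build_ngram_vocabulary(seqs)
        M = F.ngram_matrix(seqs, vocab)
        for i, s in enumerate(seqs):
            assert np.array_equal(M[i].toarray(),
                                  F.ngram_features(s, vocab).toarray())

    def test_vocabulary_deterministic(self, rng):
        seqs = ["KWKLFKKI", "GGDDEEKK"]
        assert (F.build_ngram_vocabulary(seqs)
                == F.build_ngram_vocabulary(list(seqs)))

    def test_sparse_triplet_text_roundtrip(self, tmp_path):
        import pandas as pd

        seqs = ["KWKLFKKI", "GGDDEEKK", "AAAA"]
        vocab = F.build_ngram_vocabulary(seqs)
        M = F.ngram_matrix(seqs, vocab)
        path = tmp_path / "ngrams.tsv"
        F.write_sparse_triplets(M, path)
        df = pd.read_csv(path, sep="\t", comment="#")
        assert len(df) == M.nnz
        dense = M.toarray()
        for row in df.itertuples():
            assert dense[row.row, row.col] == row.value


def exhaustive_quipt_oracle(x, y):
    """Brute force: all distinct placements of the label multiset."""
    x = np.asarray(x)
    y = np.asarray(y)
    n, n1 = len(y), int(y.sum())

    def ig(xcol, ycol):
        return float(F._information_gain(
            np.array([int(np.sum((xcol == 1) & (ycol == 1)))]),
            n, n1, int(xcol.sum()))[0])

    obs = ig(x, y)
    hits = total = 0
    for ones in itertools.combinations(range(n), n1):
        perm = np.zeros(n, dtype=int)
        perm[list(ones)] = 1
        total += 1
        if ig(x, perm) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestQuipt:
    def test_perfect_feature_hypergeometric(self):
        # the perfectly correlated AND perfectly anti-correlated tables both
        # attain the maximal information gain, so the exact permutation
        # p-value is 2 / C(10, 5) (verified by the exhaustive oracle below)
        x = [1] * 5 + [0] * 5
        p = F.quipt(x, x)
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)
        assert p == pytest.approx(exhaustive_quipt_oracle(np.array(x),
                                                          np.array(x)),
                                  abs=1e-12)

    def test_constant_feature_p_one(self):
        assert F.quipt([1] * 8, [1, 0] * 4) == 1.0
        assert F.quipt([0] * 8, [1, 0] * 4) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            F.quipt([1, 0], [1, 0, 1])

    def test_matches_exhaustive_oracle_small_n(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 2, size=n)
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            p = F.quipt(x, y)
            if x.sum() in (0, n):
                assert p == 1.0
                continue
            assert p == pytest.approx(exhaustive_quipt_oracle(x, y),
                                      abs=1e-12)

    def test_vectorized_agrees_with_scalar(self, rng):
        from scipy.sparse import csr_matrix

        n = 40
        y = rng.integers(0, 2, size=n)
        y[0], y[1] = 0, 1
        X = rng.integers(0, 2, size=(n, 25))
        ps = F.quipt_pvalues(csr_matrix(X), y)
        for j in range(25):
            assert ps[j] == pytest.approx(F.quipt(X[:, j], y), abs=1e-12)


class TestLZ:
    def test_homopolymer_less_complex_than_random(self, rng):
        rand = "".join(rng.choice(list(AMINO_ACIDS), size=64))
        assert F.lz76_complexity("A" * 64) < F.lz76_complexity(rand)

    def test_self_similarity_is_maximal(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=30))
                for _ in range(10)]
        ref = F.LZReferenceSet(seqs)
        for i, s in enumerate(seqs):
            prof = ref.profile(s).values
            assert prof[i] == pytest.approx(prof.max())

    def test_reference_size_contract(self, rng):
        ref = F.LZReferenceSet(["KWKL", "GGGG"])
        with pytest.raises(ValueError, match="expected 1000"):
            F.lz_similarity_profile("KWKL", ref)
        fv = F.lz_similarity_profile("KWKL", ref, expected_size=2)
        assert len(fv) == 2

    def test_build_reference_balanced(self, rng):
        pos = ["K" * 10] * 30
        neg = ["L" * 10] * 30
        ref = F.build_lz_reference(pos, neg, size=20, seed=1)
        assert ref.size == 20
        with pytest.raises(ValueError):
            F.build_lz_reference(pos[:2], neg, size=20, seed=1)


class TestPca:
    def test_line_data_first_component_dominates(self, rng):
        t = rng.normal(size=100)
        X = np.outer(t, [1.0, 2.0, -0.5]) + 1e-9 * rng.normal(
            size=(100, 3))
        pca, Z = F.pca_transform(X, 3)
        assert pca.explained_variance_ratio_[0] >= 0.999

    def test_train_mean_projects_to_origin(self, rng):
        X = rng.normal(size=(50, 4))
        pca, _ = F.pca_transform(X, 2)
        assert np.allclose(pca.transform(X.mean(axis=0, keepdims=True)),
                           0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(30, 5))
        pca, Z = F.pca_transform(X, 5)
        assert np.allclose(pca.inverse_transform(Z), X, atol=1e-9)

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError):
            F.pca_transform(np.ones((10, 3)), 2)
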