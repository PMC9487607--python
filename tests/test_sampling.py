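"""Negative-sampling specs, filter operators and sample assembly."""

import collections

import numpy as np
import pytest

from ampbench import sampling, seqdata
from ampbench.sampling import (SamplingSpec, alignment_identity,
                               amp_similarity_screen, builtin_specs,
                               cysteine_free_substrings, filter_by_keywords,
                               filter_by_length_range,
                               filter_by_localization,
                               greedy_identity_cluster,
                               remove_potential_amps, sample_lengths_equal,
                               sample_lengths_similar, spec_by_name)
from ampbench.seqdata import SequenceRecord


class TestBuiltinSpecs:
    # one row per published method: (name, excluded keyword count, policy,
    # range, cd-hit threshold, has whitelist, cys-free, potential-amp,
    # similarity screen, balanced)
    TABLE = {
        "Wang": ({"secreted", "antimicrobial"}, "similar_to_positive", None,
                 0.7, None, False, False, False, False),
        "CS-AMPPred": ({"antimicrobial"}, "range", (16, 90), 0.4, None,
                       False, False, False, True),
        "iAMP-2L": ({"antimicrobial", "antibiotic", "fungicide", "defensin"},
                    "range", (5, 100), 0.4, None, False, False, False,
                    False),
        "Gabere&Noble": ({"antimicrobial"}, "equal_to_positive", None, None,
                         {"golgi", "cytoplasm", "endoplasmic reticulum",
                          "mitochondria"}, False, False, False, False),
        "AMAP": ({"antimicrobial"}, "similar_to_positive", None, 0.4, None,
                 False, False, False, False),
        "AMPScannerV2": ({"antimicrobial", "antibiotic", "antiviral",
                          "fungicide", "secreted"}, "equal_to_positive",
                         None, None, {"cytoplasm"}, False, False, True,
                         True),
        "dbAMP": ({"transmembrane", "toxin", "secreted", "defensin",
                   "antimicrobial", "antibiotic", "antiviral", "fungicide"},
                  "range", (10, 100), 0.4, None, False, False, False, False),
        "Witten&Witten": ({"antimicrobial", "antibiotic", "antiviral",
                           "fungicide", "secreted"}, "equal_to_positive",
                          None, 0.4, {"cytoplasm"}, True, False, False,
                          True),
        "AmpGram": ({"antimicrobial", "antibacterial", "antiviral",
                     "fungicide", "secreted", "transit peptide"},
                    "equal_to_positive", None, None, None, False, False,
                    False, True),
        "ampir-mature": ({"antimicrobial"}, "range", (10, 40), 0.9, None,
                         False, False, False, False),
        "AMPlify": ({"antimicrobial", "antibiotic", "defence", "defensin",
                     "bacteriocin", "fungicide"}, "equal_to_positive", None,
                    None, None, False, True, False, True),
    }

    def test_eleven_specs(self):
        assert len(builtin_specs()) == 11

    @pytest.mark.parametrize("name", sorted(TABLE))
    def test_spec_matches_published_row(self, name):
        (kw, policy, rng_, thr, whitelist, cys, pot, screen,
         balanced) = self.TABLE[name]
        spec = spec_by_name(name)
        assert spec.excluded_keywords == frozenset(kw)
        assert spec.length_policy == policy
        assert spec.length_range == rng_
        assert spec.clustering_threshold == thr
        assert spec.localization_whitelist == (
            frozenset(whitelist) if whitelist else None)
        assert spec.cysteine_free_substrings is cys
        assert spec.remove_potential_amps is pot
        assert spec.amp_similarity_screen is screen
        assert spec.balanced is balanced

    def test_five_methods_are_balanced(self):
        balanced = {s.name for s in builtin_specs() if s.balanced}
        assert balanced == {"CS-AMPPred", "AMPScannerV2", "Witten&Witten",
                            "AmpGram", "AMPlify"}

    def test_every_method_excludes_antimicrobial(self):
        for spec in builtin_specs():
            assert ("antimicrobial" in spec.excluded_keywords
                    or "antibacterial" in spec.excluded_keywords)

    def test_structured_text_roundtrip(self):
        import yaml

        for spec in builtin_specs():
            dumped = yaml.safe_load(yaml.safe_dump(spec.to_dict()))
            assert SamplingSpec.from_dict(dumped) == spec


class TestFilters:
    def test_keyword_exclusion(self, toy_records):
        out = filter_by_keywords(toy_records, {"antimicrobial"})
        assert {r.id for r in out} == {"b", "c", "d", "e"}

    def test_empty_exclusion_is_identity(self, toy_records):
        assert filter_by_keywords(toy_records, set()) == toy_records

    def test_keyword_filter_matches_brute_force(self, rng):
        terms = ["antimicrobial", "toxin", "secreted"]
        db = [SequenceRecord(f"r{i}", "KKLL",
                             keywords={t for t in terms
                                       if rng.random() < 0.2})
              for i in range(100)]
        excluded = {"toxin", "secreted"}
        expected = sum(1 for r in db if not (r.keywords & excluded))
        assert len(filter_by_keywords(db, excluded)) == expected

    def test_localization_whitelist(self, toy_records):
        out = filter_by_localization(toy_records, {"cytoplasm"})
        assert {r.id for r in out} == {"a", "e"}
        # empty localization never intersects
        assert all(r.localization for r in out)

    def test_length_range_boundaries(self):
        db = [SequenceRecord("x", "A" * n) for n in (4, 5, 16, 90, 91, 100)]
        out = filter_by_length_range(db, 16, 90)
        assert sorted(len(r) for r in out) == [16, 90]
        out2 = filter_by_length_range(db, 5, 100)
        assert sorted(len(r) for r in out2) == [5, 16, 90, 91, 100]

    def test_potential_amp_screen(self):
        db = [SequenceRecord("a", "KKLL", keywords={"bacteriocin"}),
              SequenceRecord("b", "KKLL", keywords={"toxin"}),
              SequenceRecord("c", "KKLL", keywords={"defence"})]
        out = remove_potential_amps(db)
        assert [r.id for r in out] == ["b"]


class TestCysteineFreeSubstrings:
    def test_only_cysteine_free_window_chosen(self, rng):
        rec = SequenceRecord("x", "KKCKKK")
        for _ in range(20):
            coords = cysteine_free_substrings(rec, 3, rng)
            start, end = coords
            assert "C" not in rec.residues[start:end]
            assert end - start == 3

    def test_all_cysteine_returns_none(self, rng):
        assert cysteine_free_substrings(SequenceRecord("x", "CCCC"), 2,
                                        rng) is None

    def test_start_count_matches_enumeration(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 8))
            seq = "".join(rng.choice(list("ACK"), size=20))
            starts = sampling._cysteine_free_starts(seq, L)
            brute = [i for i in range(len(seq) - L + 1)
                     if "C" not in seq[i:i + L]]
            assert starts == brute


class TestAmpSimilarityScreen:
    def test_exact_match_removed(self):
        pos = [SequenceRecord("p", "KWKLFKKIEK")]
        cand = [SequenceRecord("c", "KWKLFKKIEK")]
        assert amp_similarity_screen(cand, pos) == []

    def test_shared_10mer_removed_but_9mer_kept(self):
        pos = [SequenceRecord("p", "KWKLFKKIEKVGQNIR")]
        shares10 = SequenceRecord("a", "AAAA" + "KWKLFKKIEK" + "GGGG")
        shares9 = SequenceRecord("b", "AAAA" + "KWKLFKKIE" + "GGGGG")
        out = amp_similarity_screen([shares10, shares9], pos)
        assert [r.id for r in out] == ["b"]

    def test_kmer_rule_matches_brute_force(self, rng):
        def kmers(s, k=10):
            return {s[i:i + k] for i in range(len(s) - k + 1)}

        pos = [SequenceRecord(f"p{i}", "".join(
            rng.choice(list(seqdata.AMINO_ACIDS), size=30)))
            for i in range(5)]
        cands = [SequenceRecord(f"c{i}", "".join(
            rng.choice(list(seqdata.AMINO_ACIDS), size=25)))
            for i in range(30)]
        pos_kmers = set().union(*(kmers(p.residues) for p in pos))
        expected = [c.id for c in cands
                    if not (kmers(c.residues) & pos_kmers)
                    and c.residues not in {p.residues for p in pos}]
        got = [r.id for r in amp_similarity_screen(cands, pos)]
        assert got == expected


class TestIdentityAndClustering:
    def test_identity_examples(self):
        assert alignment_identity("KKKKKKKKKK", "KKKKKKKKKR") == 0.9
        assert alignment_identity("KKKK", "LLLL") == 0.0
        assert alignment_identity("KWKL", "KWKL") == 1.0
        # containment counts as full identity of the shorter
        assert alignment_identity("KWKL", "AAKWKLAA") == 1.0

    def test_duplicates_collapse(self):
        recs = [SequenceRecord("a", "KWKLFKKI"),
                SequenceRecord("b", "KWKLFKKI"),
                SequenceRecord("c", "KWKLFKKI")]
        assert len(greedy_identity_cluster(recs, 0.9)) == 1

    def test_disjoint_alphabet_never_clusters(self):
        recs = [SequenceRecord("a", "KKKKK"), SequenceRecord("b", "LLLLL")]
        for thr in (0.1, 0.4, 0.9, 1.0):
            assert len(greedy_identity_cluster(recs, thr)) == 2

    def test_single_mismatch_boundary_thresholds(self):
        recs = [SequenceRecord("a", "KKKKKKKKKK"),
                SequenceRecord("b", "KKKKKKKKKR")]
        assert len(greedy_identity_cluster(recs, 0.9)) == 1   # 0.9 >= 0.9
        assert len(greedy_identity_cluster(recs, 0.95)) == 2  # 0.9 < 0.95

    def test_representatives_longest_first(self):
        recs = [SequenceRecord("short", "KWKLF"),
                SequenceRecord("long", "KWKLFKKIEKKWKLF")]
        reps = greedy_identity_cluster(recs, 0.8)
        assert [r.id for r in reps] == ["long"]


class TestFragmentSampling:
    def _db(self, rng, n=40, lo=30, hi=120):
        return [SequenceRecord(f"d{i}", "".join(
            rng.choice(list(seqdata.AMINO_ACIDS),
                       size=int(rng.integers(lo, hi)))))
            for i in range(n)]

    def test_equal_lengths_exact_multiset(self, rng):
        db = self._db(rng)
        target = [5, 10, 10, 17, 25]
        frags = sample_lengths_equal(db, target, seed=5)
        assert sorted(len(f) for f in frags) == sorted(target)

    def test_forced_whole_record_fragment(self):
        db = [SequenceRecord("only", "KWKLFKKI")]
        frags = sample_lengths_equal(db, [8], seed=0)
        assert frags[0].residues == "KWKLFKKI"

    def test_unsatisfiable_length_errors(self, rng):
        db = self._db(rng, n=5, lo=10, hi=20)
        with pytest.raises(ValueError, match="500"):
            sample_lengths_equal(db, [500], seed=0)

    def test_seeded_runs_identical(self, rng):
        db = self._db(rng)
        a = sample_lengths_equal(db, [8, 12, 30], seed=11)
        b = sample_lengths_equal(db, [8, 12, 30], seed=11)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_similar_without_threshold_degenerates_to_equal(self, rng):
        db = self._db(rng)
        frags = sample_lengths_similar(db, [7, 9, 13], seed=2)
        assert sorted(len(f) for f in frags) == [7, 9, 13]

    def test_similar_clustering_only_shrinks(self, rng):
        db = self._db(rng)
        target = [10] * 30
        frags = sample_lengths_similar(db, target, seed=2,
                                       clustering_threshold=0.4)
        assert len(frags) <= 30

    def test_similar_ks_distance_small(self, small_split, small_background):
        from scipy.stats import ks_2samp

        lengths = small_split.train_lengths
        frags = sample_lengths_similar(small_background, lengths, seed=3,
                                       clustering_threshold=0.7)
        stat = ks_2samp([len(f) for f in frags], lengths).statistic
        assert stat <= 0.2


class TestAssembleNegativeSample:
    def test_balanced_equal_spec_matches_positive_multiset(
            self, small_split, small_background):
        ds = sampling.assemble_negative_sample(
            spec_by_name("AmpGram"), small_background, small_split,
            n_replicates=1, seed=5)[0]
        assert (collections.Counter(len(r) for r in ds.neg_train)
                == collections.Counter(small_split.train_lengths))
        assert (collections.Counter(len(r) for r in ds.neg_bench)
                == collections.Counter(small_split.bench_lengths))

    def test_localization_stage_failure_names_stage(self, small_split):
        db = [SequenceRecord(f"r{i}", "KWKLFKKI" * 30) for i in range(50)]
        with pytest.raises(ValueError, match="localization"):
            sampling.assemble_negative_sample(
                spec_by_name("Gabere&Noble"), db, small_split,
                n_replicates=1, seed=1)

    def test_replicates_distinct_and_deterministic(
            self, small_split, small_background):
        spec = spec_by_name("AmpGram")
        runs = [sampling.assemble_negative_sample(
            spec, small_background, small_split, n_replicates=3, seed=9)
            for _ in range(2)]
        for d1, d2 in zip(*runs):
            assert ([r.residues for r in d1.neg_train]
                    == [r.residues for r in d2.neg_train])
        sets = [frozenset(r.residues for r in d.neg_train)
                for d in runs[0]]
        assert len(set(sets)) == 3

    def test_target_size_unreachable_reports_maximum(self, small_split):
        db = [SequenceRecord(f"r{i}",
                             "".join(np.random.default_rng(i).choice(
                                 list(seqdata.AMINO_ACIDS), size=50)))
              for i in range(30)]
        with pytest.raises(ValueError, match="at most"):
            sampling.assemble_negative_sample(
                spec_by_name("CS-AMPPred"), db, small_split,
                n_replicates=1, seed=1)

    def test_provenance_recorded_for_every_negative(
            self, small_split, small_background):
        ds = sampling.assemble_negative_sample(
            spec_by_name("Wang"), small_background, small_split,
            n_replicates=1, seed=2)[0]
        for rec in ds.neg_train + ds.neg_bench:
            parent, start, end = ds.provenance[rec.id]
            assert end - start == len(rec)
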