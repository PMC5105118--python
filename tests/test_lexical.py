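"""Weighted alignment, calibrated doculect distances, and ASJP parsing."""

import itertools

import numpy as np
import pytest

from cranolex import synthetic
from cranolex.errors import (
    FormatError,
    InvalidParameterError,
    NoCandidatesError,
    UndefinedDistanceError,
)
from cranolex.lexical import (
    ASJP_ALPHABET,
    CONCEPTS,
    Doculect,
    PopulationMeta,
    WeightMatrix,
    align_score,
    align_words,
    doculect_distance,
    doculect_similarity,
    estimate_weights,
    family_distance,
    parse_asjp,
    population_distance,
    read_weight_matrix,
    select_candidates,
    uniform_weights,
    write_asjp,
    write_weight_matrix,
)


def brute_force_best_score(a, b, w):
    """Exhaustive alignment enumeration (linear gap model, go == ge)."""
    assert w.gap_open == w.gap_extend
    gap = w.gap_open

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, w.weight(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestAlignWords:
    def test_self_alignment_all_matches_no_gaps(self, toy_weights):
        res = align_words("abcab", "abcab", toy_weights)
        assert res.score == pytest.approx(2.0 * 5)
        assert all(x == y for x, y in res.aligned_pairs)

    def test_gapless_recovery_of_inputs(self, toy_weights):
        res = align_words("abc", "cab", toy_weights)
        assert res.aligned_a.replace("-", "") == "abc"
        assert res.aligned_b.replace("-", "") == "cab"

    def test_score_equals_column_sum(self, toy_weights):
        res = align_words("aabc", "abcc", toy_weights)
        total = 0.0
        for x, y in res.aligned_pairs:
            if x == "-" or y == "-":
                total += toy_weights.gap_open
            else:
                total += toy_weights.weight(x, y)
        assert total == pytest.approx(res.score)

    def test_matches_brute_force_on_random_pairs(self, toy_weights, rng):
        strings = ["".join(rng.choice(list("abc"), size=4)) for _ in range(12)]
        for a, b in itertools.combinations(strings, 2):
            assert align_score(a, b, toy_weights) == pytest.approx(
                brute_force_best_score(a, b, toy_weights)
            )

    def test_common_correspondence_outweighs_unrelated_mismatch(self):
        # the published worked example pattern: cognates with regular sound
        # correspondences (hEnd-hant) score far above chance pairs (hEnd-mano)
        w = {}
        for a in ASJP_ALPHABET:
            for b in ASJP_ALPHABET:
                w[(a, b)] = 5.0 if a == b else -6.0
        for pair in [("E", "a"), ("d", "t"), ("e", "i"), ("o", "u")]:
            w[pair] = w[pair[::-1]] = 2.4
        wm = WeightMatrix(w, gap_open=-7.0, gap_extend=-7.0)
        cognate = align_words("hEnd", "hant", wm)
        chance = align_words("hEnd", "mano", wm)
        assert cognate.score > chance.score
        assert cognate.aligned_pairs == [("h", "h"), ("E", "a"), ("n", "n"), ("d", "t")]

    def test_empty_string_rejected(self, toy_weights):
        with pytest.raises(InvalidParameterError):
            align_words("", "abc", toy_weights)

    def test_unknown_symbol_rejected(self, toy_weights):
        with pytest.raises(InvalidParameterError):
            align_words("axc", "abc", toy_weights)

    def test_affine_gaps_prefer_one_long_run(self):
        w = {(a, b): (3.0 if a == b else -1.0) for a in "ab" for b in "ab"}
        wm = WeightMatrix(w, gap_open=-4.0, gap_extend=-0.5)
        res = align_words("aaaa", "aabbbaa", wm)
        gaps_a = "".join("g" if x == "-" else "." for x, _ in res.aligned_pairs)
        assert "ggg" in gaps_a  # single length-3 run, not split gaps


class TestDoculectSimilarity:
    def make_doculect(self, name, words):
        return Doculect(name=name, words={c: list(ws) for c, ws in words.items()})

    def test_identical_doculects_with_separated_scores_distance_zero(self, toy_weights):
        words = {"I": ["aaaa"], "you": ["bbbb"], "we": ["cccc"]}
        d = self.make_doculect("x", words)
        sim, dist = doculect_similarity(d, self.make_doculect("y", words), toy_weights)
        assert sim == pytest.approx(1.0)
        assert dist == pytest.approx(0.0)

    def test_no_shared_concepts_is_undefined(self, toy_weights):
        d1 = self.make_doculect("x", {"I": ["aa"]})
        d2 = self.make_doculect("y", {"you": ["bb"]})
        with pytest.raises(UndefinedDistanceError):
            doculect_similarity(d1, d2, toy_weights)

    def test_three_concept_toy_matches_exhaustive_pool_oracle(self, toy_weights):
        d1 = self.make_doculect("x", {"I": ["ab"], "you": ["bc", "ca"], "we": ["aa"]})
        d2 = self.make_doculect("y", {"I": ["ac"], "you": ["cc"], "we": ["ba"]})
        sim, dist = doculect_similarity(d1, d2, toy_weights)

        def s(a, b):
            return brute_force_best_score(a, b, toy_weights)

        syn = {
            "I": s("ab", "ac"),
            "you": max(s("bc", "cc"), s("ca", "cc")),
            "we": s("aa", "ba"),
        }
        pool = []
        for c1, ws1 in d1.words.items():
            for c2, ws2 in d2.words.items():
                if c1 == c2:
                    continue
                pool.extend(s(x, y) for x in ws1 for y in ws2)
        expected = np.mean(
            [np.mean([p < syn[c] for p in pool]) for c in ("I", "you", "we")]
        )
        assert sim == pytest.approx(expected)
        assert dist == pytest.approx(1.0 - expected)

    def test_distance_symmetric_and_bounded(self, toy_weights, rng):
        def random_doculect(name):
            return Doculect(
                name=name,
                words={
                    c: ["".join(rng.choice(list("abc"), size=3))]
                    for c in CONCEPTS[:10]
                },
            )

        d1, d2 = random_doculect("x"), random_doculect("y")
        dist_xy = doculect_distance(d1, d2, toy_weights)
        dist_yx = doculect_distance(d2, d1, toy_weights)
        assert 0.0 <= dist_xy <= 1.0
        assert dist_xy == pytest.approx(dist_yx)


class TestSelectCandidates:
    def doculects(self):
        return [
            Doculect("Tamil", "Dra.SOUTHERN", lat=10.0, lon=78.0),
            Doculect("Kannada", "Dra.SOUTHERN", lat=13.0, lon=76.0),
            Doculect("Tokyo_Japanese", "Jap.JAPANESE", lat=35.7, lon=139.7, island="Honshu"),
            Doculect("Kyoto_Japanese", "Jap.JAPANESE", lat=35.0, lon=135.8, island="Honshu"),
            Doculect("Ainu", "Ain.AINU", lat=43.0, lon=143.0, island="Hokkaido"),
        ]

    def test_ethnonym_restricts_to_named_doculect(self):
        out = select_candidates(
            PopulationMeta("South India", ethnonyms=("Tamil",)), self.doculects()
        )
        assert [d.name for d in out] == ["Tamil"]

    def test_island_restricts_to_island_doculects(self):
        out = select_candidates(
            PopulationMeta("Japan", islands=("Honshu",)), self.doculects()
        )
        assert {d.name for d in out} == {"Tokyo_Japanese", "Kyoto_Japanese"}

    def test_coordinate_heuristic_uses_500km_radius(self):
        # Kannada at ~330 km from (11, 77); Tokyo at thousands of km
        out = select_candidates(
            PopulationMeta("SI", lat=11.0, lon=77.0), self.doculects()
        )
        assert {d.name for d in out} == {"Tamil", "Kannada"}

    def test_no_candidates_raises(self):
        with pytest.raises(NoCandidatesError):
            select_candidates(
                PopulationMeta("Atlantis", lat=0.0, lon=-40.0), self.doculects()
            )


class TestAggregation:
    def test_single_candidates_equal_doculect_distance(self, toy_weights):
        d1 = Doculect("x", words={"I": ["ab"], "you": ["bc"]})
        d2 = Doculect("y", words={"I": ["ac"], "you": ["cb"]})
        assert population_distance([d1], [d2], toy_weights) == pytest.approx(
            doculect_distance(d1, d2, toy_weights)
        )

    def test_two_by_two_candidates_mean_of_four(self, toy_weights):
        ds = [
            Doculect(f"d{i}", words={"I": [w1], "you": [w2]})
            for i, (w1, w2) in enumerate(
                [("ab", "bc"), ("ba", "cb"), ("ac", "ca"), ("cc", "aa")]
            )
        ]
        expected = np.mean(
            [doculect_distance(a, b, toy_weights) for a in ds[:2] for b in ds[2:]]
        )
        assert population_distance(ds[:2], ds[2:], toy_weights) == pytest.approx(expected)

    def test_population_distance_symmetric(self, toy_weights):
        ds = [
            Doculect(f"d{i}", words={"I": [w]})
            for i, w in enumerate(["ab", "ba", "ac"])
        ]
        # need >= 2 concepts for a calibration pool; extend words
        for d, w2 in zip(ds, ["ca", "bb", "cb"]):
            d.words["you"] = [w2]
        assert population_distance(ds[:1], ds[1:], toy_weights) == pytest.approx(
            population_distance(ds[1:], ds[:1], toy_weights)
        )

    def test_family_distance_mean_of_cross_pairs(self, toy_weights):
        fam_a = [
            Doculect("a1", "FamA.X", words={"I": ["ab"], "you": ["bc"]}),
            Doculect("a2", "FamA.X", words={"I": ["ba"], "you": ["cb"]}),
        ]
        fam_b = [
            Doculect("b1", "FamB.Y", words={"I": ["cc"], "you": ["aa"]}),
            Doculect("b2", "FamB.Y", words={"I": ["ac"], "you": ["ca"]}),
            Doculect("b3", "FamB.Y", words={"I": ["cb"], "you": ["ab"]}),
        ]
        expected = np.mean(
            [doculect_distance(a, b, toy_weights) for a in fam_a for b in fam_b]
        )
        assert family_distance(fam_a, fam_b, toy_weights) == pytest.approx(expected)

    def test_family_distance_invariant_to_member_order(self, toy_weights):
        fam_a = [
            Doculect("a1", "FamA.X", words={"I": ["ab"], "you": ["bc"]}),
            Doculect("a2", "FamA.X", words={"I": ["ba"], "you": ["cb"]}),
        ]
        fam_b = [
            Doculect("b1", "FamB.Y", words={"I": ["cc"], "you": ["aa"]}),
            Doculect("b2", "FamB.Y", words={"I": ["ac"], "you": ["ca"]}),
        ]
        assert family_distance(fam_a, fam_b, toy_weights) == pytest.approx(
            family_distance(fam_a[::-1], fam_b[::-1], toy_weights)
        )

    def test_overlapping_families_rejected(self, toy_weights):
        d = Doculect("a1", "FamA.X", words={"I": ["ab"], "you": ["bc"]})
        with pytest.raises(InvalidParameterError):
            family_distance([d], [d], toy_weights)


class TestEstimateWeights:
    def test_identical_cooccurrence_maximizes_identity_weights(self):
        related = [("aba", "aba"), ("bab", "bab"), ("aab", "aab")] * 5
        background = [("aaa", "bbb"), ("bba", "aab"), ("ab", "ba")] * 5
        w = estimate_weights(related, background, alphabet="ab", n_iter=2)
        assert w.weight("a", "a") > w.weight("a", "b")
        assert w.weight("b", "b") > w.weight("a", "b")

    def test_dominant_substitution_ranks_above_other_mismatches(self):
        # cognates where x->y substitution is systematic
        related = [("axa", "aya"), ("xax", "yay"), ("xxa", "yya")] * 10
        background = [("aaa", "yyy"), ("xxx", "aaa"), ("ax", "ya")] * 10
        w = estimate_weights(related, background, alphabet="axy", n_iter=2)
        others = [
            w.weight(p, q)
            for p in "axy"
            for q in "axy"
            if p < q and {p, q} != {"x", "y"}
        ]
        assert w.weight("x", "y") > max(others)

    def test_deterministic_for_fixed_training_set(self):
        related = [("ab", "ab"), ("ba", "ba")] * 3
        background = [("aa", "bb")] * 3
        w1 = estimate_weights(related, background, alphabet="ab")
        w2 = estimate_weights(related, background, alphabet="ab")
        assert w1.sound_pair_weights == w2.sound_pair_weights

    def test_empty_training_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_weights([], [("aa", "bb")], alphabet="ab")


class TestAsjpIO:
    def test_minimal_file_parses(self, tmp_path):
        content = (
            "TAMIL{Dra.SOUTHERN}\n"
            "  10.0000 78.0000\n"
            "1 I\tna\n"
            "2 you\tni, nir\n"
            "5 two\tiru\n"
        )
        path = tmp_path / "l.asjp"
        path.write_text(content)
        (d,) = parse_asjp(path)
        assert d.name == "TAMIL"
        assert d.family == "Dra"
        assert d.lat == pytest.approx(10.0)
        assert d.words["I"] == ["na"]
        assert d.words["you"] == ["ni", "nir"]
        assert d.words["two"] == ["iru"]

    def test_synonyms_split_on_comma(self, tmp_path):
        path = tmp_path / "l.asjp"
        path.write_text("X{F.G}\n 0 0\n1 I\tna, ne, no\n")
        (d,) = parse_asjp(path)
        assert d.words["I"] == ["na", "ne", "no"]

    def test_missing_and_loan_entries_handled(self, tmp_path):
        path = tmp_path / "l.asjp"
        path.write_text("X{F.G}\n 0 0\n1 I\tXXX\n2 you\t%niu\n")
        (d,) = parse_asjp(path)
        assert "I" not in d.words
        assert d.words["you"] == ["niu"]

    def test_malformed_concept_index_reports_line(self, tmp_path):
        path = tmp_path / "l.asjp"
        path.write_text("X{F.G}\n 0 0\nzz I\tna\n")
        with pytest.raises(FormatError, match=":3"):
            parse_asjp(path)

    def test_symbol_outside_asjpcode_rejected(self, tmp_path):
        path = tmp_path / "l.asjp"
        path.write_text("X{F.G}\n 0 0\n1 I\tnØ\n")
        with pytest.raises(FormatError):
            parse_asjp(path)

    def test_synthetic_fixture_round_trips_byte_stable(self, tmp_path, small_params, small_world):
        doculects, _ = synthetic.simulate_wordlists(small_world, small_params)
        path1 = tmp_path / "a.asjp"
        path2 = tmp_path / "b.asjp"
        write_asjp(list(doculects.values()), path1)
        write_asjp(parse_asjp(path1), path2)
        assert path1.read_bytes() == path2.read_bytes()

    def test_weight_matrix_tsv_round_trip(self, tmp_path, toy_weights):
        path = tmp_path / "w.tsv"
        write_weight_matrix(toy_weights, path)
        back = read_weight_matrix(path)
        assert back.gap_open == toy_weights.gap_open
        for key, v in toy_weights.sound_pair_weights.items():
            assert back.weight(*key) == pytest.approx(v)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="abc", min_size=1, max_size=5),
        b=st.text(alphabet="abc", min_size=1, max_size=5),
    )
    def test_alignment_score_properties(a, b):
        """Optimality vs brute force, symmetry, and gap-recovery hold for
        arbitrary short strings over the toy alphabet."""
        w = WeightMatrix(
            {(x, y): (2.0 if x == y else -1.0) for x in "abc" for y in "abc"},
            gap_open=-2.5,
            gap_extend=-2.5,
        )
        score = align_score(a, b, w)
        assert score == pytest.approx(brute_force_best_score(a, b, w))
        assert score == pytest.approx(align_score(b, a, w))
        res = align_words(a, b, w)
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
        assert res.score == pytest.approx(score)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
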