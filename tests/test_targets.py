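"""Seed matching, duplex alignment, accessibility energy, and consensus."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from wingnet import targets
from wingnet.simulate import reverse_complement_rna

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

rna = st.text(alphabet="ACGU", min_size=0, max_size=60)


class TestSeedSites:
    def test_let7_8mer_hand_example(self):
        sites = targets.find_seed_sites(LET7, "GGGG" + "CUACCUCA" + "GGGG")
        assert len(sites) == 1
        s = sites[0]
        assert s.seed_class == "8mer"
        assert (s.start, s.end) == (4, 12)

    def test_no_complement_no_sites(self):
        assert targets.find_seed_sites(LET7, "A" * 50) == []

    def test_dna_input_accepted(self):
        sites = targets.find_seed_sites(LET7, "ggggCTACCTCAgggg")
        assert sites[0].seed_class == "8mer"

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            targets.find_seed_sites(LET7, "ACGTN")
        with pytest.raises(ValueError):
            targets.find_seed_sites("UGAGG", "ACGU")  # too short

    @pytest.mark.parametrize("cls,site", [
        ("8mer", "CUACCUCA"),
        ("7mer-m8", "CUACCUCG"),
        ("7mer-A1", "UACCUCA"),
        ("6mer", "UACCUCG"),
    ])
    def test_class_assignment(self, cls, site):
        sites = targets.find_seed_sites(LET7, "GG" + site + "GG")
        assert [s.seed_class for s in sites] == [cls]

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = "".join(rng.choice(list("ACGU"), size=int(rng.integers(17, 26))))
            u = "".join(rng.choice(list("ACGU"), size=int(rng.integers(10, 120))))
            got = sorted((s.core_start, s.seed_class)
                         for s in targets.find_seed_sites(m, u))
            assert got == oracles.brute_force_seed_sites(m, u)

    def test_reverse_complement_mirrors_coordinates(self):
        """Metamorphic: a seed-complementary core at position p means the
        reverse-complemented UTR carries the seed itself at the mirrored
        coordinate L - 6 - p (anti-parallel orientation contract)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = "".join(rng.choice(list("ACGU"), size=22))
            u = "".join(rng.choice(list("ACGU"), size=80))
            planted = u[:30] + reverse_complement_rna(m[1:7]) + u[36:]
            sites = targets.find_seed_sites(m, planted)
            assert any(s.core_start == 30 for s in sites)
            rc = reverse_complement_rna(planted)
            L = len(planted)
            for s in sites:
                mirrored = L - 6 - s.core_start
                assert rc[mirrored : mirrored + 6] == m[1:7]


class TestDuplex:
    def test_perfect_complement_scores_145(self):
        assert targets.duplex_score(LET7, reverse_complement_rna(LET7)) == 145.0

    def test_empty_window_scores_zero(self):
        assert targets.duplex_score(LET7, "") == 0.0

    def test_window_length_validated(self):
        with pytest.raises(ValueError):
            targets.duplex_score(LET7, "ACGU" * 12)

    def test_matches_recursion_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            na = int(rng.integers(8, 26))
            nb = int(rng.integers(max(3, na - 5), min(31, na + 16)))
            a = "".join(rng.choice(list("ACGU"), size=na))
            b = "".join(rng.choice(list("ACGU"), size=nb))
            assert targets._gotoh_local(a, b) == pytest.approx(
                oracles.local_affine_oracle(a, b)
            )

    def test_score_nonnegative(self):
        assert targets.duplex_score("UUUUUUUUUUUUUUUUUU", "UUUUUUUUUUUUUU") >= 0


class TestEnergy:
    def test_poly_a_context_has_zero_opening_cost(self):
        site_seq = (reverse_complement_rna(LET7[1:8]) + "A").replace("U", "T")
        utr = "A" * 20 + site_seq + "A" * 20
        site = targets.find_seed_sites(LET7, utr)[0]
        dgd, dgo, ddg = targets.delta_delta_g(LET7, utr, site)
        assert dgo == 0.0
        assert ddg == dgd
        assert dgd <= 0.0

    def test_dg_open_nonnegative_on_random_windows(self):
        rng = np.random.default_rng(9)
        n_checked = 0
        for _ in range(500):
            u = "".join(rng.choice(list("ACGU"), size=60))
            m = "".join(rng.choice(list("ACGU"), size=21))
            planted = u[:25] + reverse_complement_rna(m[1:7]) + u[31:]
            for site in targets.find_seed_sites(m, planted):
                _, dgo, ddg = targets.delta_delta_g(m, planted, site)
                assert dgo >= -1e-9
                assert ddg <= 0.0 + 1e-9 or dgo > 0
                n_checked += 1
        assert n_checked >= 500

    def test_mfe_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 21))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert targets.structure_mfe(seq) == pytest.approx(
                oracles.brute_force_mfe(seq)
            )
            forb = frozenset(range(2, min(8, n)))
            assert targets.structure_mfe(seq, forbidden=forb) == pytest.approx(
                oracles.brute_force_mfe(seq, forb)
            )

    def test_negative_flank_rejected(self):
        site = targets.TargetSite("m", "g", 0, 6, 0, "6mer")
        with pytest.raises(ValueError):
            targets.delta_delta_g(LET7, "U" * 30, site, flank=-1)

    def test_ddg_invariant(self):
        """ddG <= dG_duplex because dG_open >= 0."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            u = "".join(rng.choice(list("ACGU"), size=70))
            m = "".join(rng.choice(list("ACGU"), size=20))
            planted = u[:30] + reverse_complement_rna(m[1:]) + "A" + u[55:]
            for site in targets.find_seed_sites(m, planted):
                dgd, dgo, ddg = targets.delta_delta_g(m, planted, site)
                assert ddg <= dgd + 1e-12


class TestConsensus:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(21)
        m = "U" + "".join(rng.choice(list("ACGU"), size=21))
        u = "".join(rng.choice(list("ACGT"), size=200))
        site = (reverse_complement_rna(m[1:]) + "A").replace("U", "T")
        utr = u[:60] + site + u[60 + len(site):]
        return m, utr

    def test_planted_pair_reaches_consensus(self, planted):
        m, utr = planted
        res = targets.consensus_targets({"mir": m}, {"g": utr})
        assert ("mir", "g") in res.pairs

    def test_consensus_subset_of_each_method(self, small_truth):
        matures = {x.id: x.mature for x in small_truth.mirnas}
        utrs = dict(list(small_truth.utrs.items())[:40])
        res = targets.consensus_targets(matures, utrs)
        for method_pairs in res.per_method.values():
            assert res.pairs <= method_pairs

    def test_shuffled_utrs_destroy_planted_consensus(self, small_truth):
        matures = {x.id: x.mature for x in small_truth.mirnas}
        planted_genes = {p.gene for p in small_truth.pairs}
        utrs = {g: small_truth.utrs[g] for g in planted_genes}
        res = targets.consensus_targets(matures, utrs)
        planted_found = res.pairs & small_truth.regulatory_pairs
        assert len(planted_found) == len(small_truth.pairs)
        rng = np.random.default_rng(0)
        shuffled = {
            g: "".join(rng.permutation(list(seq))) for g, seq in utrs.items()
        }
        res_sh = targets.consensus_targets(matures, shuffled)
        assert len(res_sh.pairs & small_truth.regulatory_pairs) < len(small_truth.pairs)
        assert len(res_sh.pairs) <= min(
            len(v) for v in res_sh.per_method.values()
        )

    def test_relaxing_thresholds_never_shrinks_consensus(self, small_truth):
        matures = {x.id: x.mature for x in list(small_truth.mirnas)[:8]}
        utrs = dict(list(small_truth.utrs.items())[:30])
        strict = targets.consensus_targets(
            matures, utrs, targets.ConsensusThresholds())
        for looser in (
            targets.ConsensusThresholds(min_seed_class="6mer"),
            targets.ConsensusThresholds(min_duplex_score=40.0),
            targets.ConsensusThresholds(max_ddg=-2.0),
        ):
            assert strict.pairs <= targets.consensus_targets(
                matures, utrs, looser).pairs

    @given(rna, rna)
    def test_seed_finder_never_crashes_and_agrees_with_oracle(self, m, u):
        if len(m) < 8:
            return
        got = sorted((s.core_start, s.seed_class)
                     for s in targets.find_seed_sites(m, u))
        assert got == oracles.brute_force_seed_sites(m, u)
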