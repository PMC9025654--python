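"""PSSM training, motif scoring and k-mer filtering against naive oracles."""

import math

import numpy as np
import pytest

from introspect import (
    AMINO_ACIDS,
    DataError,
    MotifSpec,
    ProteinRecord,
    Pssm,
    background_frequencies,
    filter_kmers,
    read_pssm,
    sample_motif_peptides,
    score_peptide,
    score_with_deletions,
    train_pssm,
    write_pssm,
)
from introspect.synthetic import random_peptides


def naive_train(peptides, background, omega, form="log_odds"):
    """Independent oracle: counting and the scoring formula in pure Python."""
    L = len(peptides[0])
    matrix = [[0.0] * 20 for _ in range(L)]
    for i in range(L):
        for a, residue in enumerate(AMINO_ACIDS):
            f = sum(1 for p in peptides if p[i] == residue) / len(peptides)
            b = background[a]
            if form == "log_odds":
                matrix[i][a] = math.log2(((f + omega * b) / (1 + omega)) / b)
            else:
                matrix[i][a] = math.log2(f + omega * b)
    return np.array(matrix)


def naive_score(matrix, peptide):
    return sum(matrix[i][AMINO_ACIDS.index(c)] for i, c in enumerate(peptide))


class TestBackgroundFrequencies:
    def test_degenerate_composition_floored(self):
        b = background_frequencies([ProteinRecord("P1", "", "AAAA")])
        assert b[0] == pytest.approx(1 - 19e-6, rel=1e-6)
        assert (b > 0).all() and b.sum() == pytest.approx(1.0)

    def test_duplicate_proteins_do_not_bias(self):
        b = background_frequencies(
            [ProteinRecord("P1", "", "ACD"), ProteinRecord("P2", "", "ACD")]
        )
        for residue in "ACD":
            assert b[AMINO_ACIDS.index(residue)] == pytest.approx(1 / 3, rel=1e-4)

    def test_uniform_proteome_within_binomial_error(self):
        seqs = random_peptides(100, length=1000, seed=3)
        proteins = [ProteinRecord(f"P{i}", "", s) for i, s in enumerate(seqs)]
        b = background_frequencies(proteins)
        se = math.sqrt(0.05 * 0.95 / 100_000)
        assert np.abs(b - 0.05).max() < 3 * se

    def test_ambiguity_codes_excluded(self):
        b = background_frequencies([ProteinRecord("P1", "", "AXAXA")])
        assert b[0] == pytest.approx(1 - 19e-6, rel=1e-6)


class TestTrainPssm:
    @pytest.mark.parametrize("form", ["log_odds", "as_printed"])
    def test_matches_naive_oracle(self, form, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 100, 0.0, seed=5)
        pssm = train_pssm(peps, uniform_background, omega=0.1, scoring_form=form)
        oracle = naive_train(peps, uniform_background, 0.1, form)
        assert np.abs(pssm.matrix - oracle).max() < 1e-12

    def test_one_hot_limit(self, uniform_background):
        pssm = train_pssm(["ACDEFGHIK"], uniform_background, omega=1e-9)
        codes = [AMINO_ACIDS.index(c) for c in "ACDEFGHIK"]
        observed = pssm.matrix[np.arange(9), codes]
        assert observed == pytest.approx(np.log2(1 / 0.05), rel=1e-6)
        assert np.isfinite(pssm.matrix).all()

    def test_background_matching_peptides_score_zero(self, uniform_background):
        # each residue appears exactly once per position: F == B == 1/20
        peps = [AMINO_ACIDS[i:] + AMINO_ACIDS[:i] for i in range(20)]
        for omega in (0.01, 0.1, 1.0):
            pssm = train_pssm(peps, uniform_background, omega=omega)
            assert np.abs(pssm.matrix).max() < 1e-12

    def test_mixed_lengths_rejected(self, uniform_background):
        with pytest.raises(DataError):
            train_pssm(["AAAA", "AAAAA"], uniform_background)

    def test_expected_length_enforced(self, uniform_background):
        with pytest.raises(DataError):
            train_pssm(["AAAA"], uniform_background, expected_length=9)

    def test_omega_shrinks_log_odds_toward_zero(self, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 80, 0.0, seed=6)
        prev = None
        for omega in (0.05, 0.2, 1.0, 5.0):
            m = train_pssm(peps, uniform_background, omega=omega).matrix
            if prev is not None:
                assert (np.abs(m) <= np.abs(prev) + 1e-12).all()
                assert (np.sign(m) * np.sign(prev) >= 0).all()
            prev = m


class TestScorePeptide:
    def test_zero_matrix_scores_zero(self, uniform_background):
        pssm = Pssm(0, 9, np.zeros((9, 20)), uniform_background, 0.1, 1)
        assert score_peptide(pssm, "ACDEFGHIK") == 0.0

    def test_two_term_sum(self, uniform_background):
        matrix = np.zeros((2, 20))
        matrix[0, AMINO_ACIDS.index("A")] = 1.5
        matrix[1, AMINO_ACIDS.index("C")] = -0.5
        pssm = Pssm(0, 2, matrix, uniform_background, 0.1, 1)
        assert score_peptide(pssm, "AC") == pytest.approx(1.0)

    def test_vectorised_scores_match_loop_oracle(self, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 200, 0.5, seed=9)
        pssm = train_pssm(peps, uniform_background, omega=0.1)
        for pep in random_peptides(100, seed=10):
            assert score_peptide(pssm, pep) == pytest.approx(
                naive_score(pssm.matrix, pep), abs=1e-9
            )

    def test_length_mismatch_and_ambiguity_rejected(self, uniform_background):
        pssm = Pssm(0, 9, np.zeros((9, 20)), uniform_background, 0.1, 1)
        with pytest.raises(DataError):
            score_peptide(pssm, "AAAA")
        with pytest.raises(ValueError):
            score_peptide(pssm, "AXAAAAAAA")

    def test_background_sampled_peptides_score_near_zero(self, uniform_background):
        train = random_peptides(1000, seed=20)
        pssm = train_pssm(train, uniform_background, omega=0.1)
        scores = [score_peptide(pssm, p) for p in random_peptides(5000, seed=21)]
        assert abs(np.mean(scores)) < 0.2 * 9

    def test_training_peptides_outscore_background(self, uniform_background):
        for seed in (1, 2, 3):
            peps, _ = sample_motif_peptides(MotifSpec(), 100, 0.0, seed=seed)
            pssm = train_pssm(peps, uniform_background, omega=0.1)
            motif_mean = np.mean([score_peptide(pssm, p) for p in peps])
            bg_mean = np.mean(
                [score_peptide(pssm, p) for p in random_peptides(500, seed=seed + 50)]
            )
            assert motif_mean > bg_mean

    def test_deletion_alignment_score_is_max_over_placements(self, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 60, 0.0, seed=12)
        pssm = train_pssm(peps, uniform_background)
        pep10 = "A" + peps[0][:5] + "W" + peps[0][5:8] + peps[0][8]
        pep10 = pep10[:10]
        best = score_with_deletions(pssm, pep10)
        # brute force over all interior single deletions
        candidates = [
            naive_score(pssm.matrix, pep10[:i] + pep10[i + 1 :]) for i in range(1, 9)
        ]
        assert best == pytest.approx(max(candidates), abs=1e-9)


class TestFilterKmers:
    def test_exact_threshold_score_excluded(self, uniform_background):
        matrix = np.zeros((9, 20))
        matrix[0, AMINO_ACIDS.index("A")] = 0.3
        pssm = Pssm(1, 9, matrix, uniform_background, 0.1, 10)
        passing = filter_kmers({9: ["AIFQSSMTK", "CIFQSSMTK"]}, [pssm], threshold=0.3)
        assert passing == {}  # 0.3 is not > 0.3, and C scores 0

    def test_minus_infinity_threshold_is_vacuous(self, uniform_background):
        pssm = Pssm(1, 9, np.zeros((9, 20)), uniform_background, 0.1, 10)
        kmers = random_peptides(50, seed=14)
        passing = filter_kmers({9: kmers}, [pssm], threshold=-np.inf)
        assert set(passing) == set(kmers)

    def test_threshold_nesting(self, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 150, 0.0, seed=15)
        pssm = train_pssm(peps, uniform_background)
        kmers = {9: random_peptides(2000, seed=16) + peps[:50]}
        previous = None
        for threshold in (3, 1, 0.3, 0, -1):
            passing = set(filter_kmers(kmers, [pssm], threshold=threshold))
            if previous is not None:
                assert previous <= passing
            previous = passing

    def test_planted_motif_filtering(self, uniform_background):
        # sharp three-anchor motif: planted 9-mers pass, background rarely does
        spec = MotifSpec(anchors={2: ("L", 1.0), 5: ("F", 1.0), 9: ("V", 1.0)})
        planted, _ = sample_motif_peptides(spec, 200, 0.0, seed=9)
        pssm = train_pssm(planted, uniform_background, omega=0.1)
        background = random_peptides(5000, seed=90)
        passing = filter_kmers(
            {9: list(set(planted)) + background}, [pssm], threshold=0.3
        )
        assert set(planted) <= set(passing)
        bg_pass = sum(1 for p in background if p in passing)
        assert bg_pass / len(background) < 0.05

    def test_core_fallback_flagged_and_restricted(self, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 100, 0.0, seed=17)
        core = train_pssm(peps, uniform_background, cluster_id=1)
        kmers = {10: random_peptides(100, length=10, seed=18)}
        via = filter_kmers(kmers, [], threshold=-np.inf, core_fallback=[core])
        assert via and all(rec.via_core for rec in via.values())
        dropped = filter_kmers(
            {**kmers, 9: peps[:5]},
            [train_pssm(peps, uniform_background)],
            threshold=-np.inf,
            core_fallback=[core],
            fallback_lengths={9},
        )
        assert all(len(p) == 9 for p in dropped)

    def test_no_matching_model_rejected(self, uniform_background):
        pssm = Pssm(1, 9, np.zeros((9, 20)), uniform_background, 0.1, 10)
        with pytest.raises(DataError):
            filter_kmers({10: ["AAAAAAAAAA"]}, [pssm])


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path, uniform_background):
        peps, _ = sample_motif_peptides(MotifSpec(), 64, 0.1, seed=19)
        pssm = train_pssm(peps, uniform_background, omega=0.1, cluster_id=3)
        path = tmp_path / "model.pssm.tsv"
        write_pssm(pssm, path)
        loaded = read_pssm(path)
        assert loaded.cluster_id == 3
        assert loaded.length == 9
        assert loaded.omega == pssm.omega
        assert loaded.n_train == pssm.n_train
        assert loaded.scoring_form == pssm.scoring_form
        assert np.array_equal(loaded.matrix, pssm.matrix)
        assert np.array_equal(loaded.background, pssm.background)
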