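"""Positional amino-acid frequency profiles and PCC_aaf."""

import numpy as np
import pytest

from introspect import (
    AMINO_ACIDS,
    DataError,
    FrequencyProfile,
    MotifSpec,
    amino_acid_frequencies,
    pcc_aaf,
    sample_motif_peptides,
)
from introspect.synthetic import random_peptides


def naive_pcc(x_row, y_row):
    """Textbook covariance / standard deviation oracle over 20 categories."""
    mx, my = sum(x_row) / 20, sum(y_row) / 20
    cov = sum((a - mx) * (b - my) for a, b in zip(x_row, y_row)) / 20
    sx = (sum((a - mx) ** 2 for a in x_row) / 20) ** 0.5
    sy = (sum((b - my) ** 2 for b in y_row) / 20) ** 0.5
    return cov / (sx * sy)


class TestAminoAcidFrequencies:
    def test_identical_peptides_give_one_hot_rows(self):
        prof = amino_acid_frequencies(["AAA", "AAA"])
        expected = np.zeros((3, 20))
        expected[:, AMINO_ACIDS.index("A")] = 1.0
        assert np.array_equal(prof.pmf, expected)

    def test_symmetric_pair(self):
        prof = amino_acid_frequencies(["AC", "CA"])
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert prof.pmf[0, a] == prof.pmf[0, c] == 0.5
        assert prof.pmf[1, a] == prof.pmf[1, c] == 0.5

    def test_matches_counting_oracle(self):
        peps, _ = sample_motif_peptides(MotifSpec(), 500, 0.1, seed=5)
        prof = amino_acid_frequencies(peps)
        for i in range(9):
            for a, residue in enumerate(AMINO_ACIDS):
                expected = sum(1 for p in peps if p[i] == residue) / len(peps)
                assert prof.pmf[i, a] == expected

    def test_mixed_lengths_rejected(self):
        with pytest.raises(DataError):
            amino_acid_frequencies(["AAA", "AAAA"])

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            amino_acid_frequencies([])


class TestPccAaf:
    def test_self_correlation_is_one(self):
        prof = amino_acid_frequencies(random_peptides(100, seed=21))
        res = pcc_aaf(prof, prof)
        assert np.allclose(res.per_position, 1.0)
        assert res.mean == pytest.approx(1.0)

    def test_symmetry_exact(self):
        x = amino_acid_frequencies(random_peptides(200, seed=22))
        y = amino_acid_frequencies(random_peptides(200, seed=23))
        assert np.array_equal(pcc_aaf(x, y).per_position, pcc_aaf(y, x).per_position)

    def test_bounds(self):
        for seed in range(5):
            x = amino_acid_frequencies(random_peptides(50, seed=2 * seed))
            y = amino_acid_frequencies(random_peptides(50, seed=2 * seed + 1))
            vals = pcc_aaf(x, y).per_position
            assert (vals >= -1 - 1e-12).all() and (vals <= 1 + 1e-12).all()

    def test_matches_textbook_oracle(self):
        x = amino_acid_frequencies(random_peptides(1000, seed=21))
        y = amino_acid_frequencies(random_peptides(1000, seed=210))
        res = pcc_aaf(x, y)
        for i in range(9):
            assert res.per_position[i] == pytest.approx(
                naive_pcc(list(x.pmf[i]), list(y.pmf[i])), abs=1e-12
            )
        assert res.mean == pytest.approx(np.mean(res.per_position), abs=1e-12)

    def test_anchor_positions_correlate_most(self):
        spec = MotifSpec(anchors={2: ("L", 0.8), 9: ("V", 0.8)})
        a, _ = sample_motif_peptides(spec, 800, 0.0, seed=31)
        b, _ = sample_motif_peptides(spec, 800, 0.0, seed=32)
        res = pcc_aaf(amino_acid_frequencies(a), amino_acid_frequencies(b))
        anchors = [res.per_position[1], res.per_position[8]]
        others = [res.per_position[i] for i in (0, 2, 3, 4, 5, 6, 7)]
        assert min(anchors) > max(others)

    def test_zero_variance_position_reported_missing(self, caplog):
        uniform = np.full((2, 20), 0.05)
        x = FrequencyProfile(2, uniform.copy(), 10)
        one_hot = np.zeros((2, 20))
        one_hot[:, 0] = 1.0
        y = FrequencyProfile(2, one_hot, 10)
        with caplog.at_level("WARNING"):
            res = pcc_aaf(x, y)
        assert np.isnan(res.per_position).all()
        assert np.isnan(res.mean)
        assert any("zero variance" in r.message for r in caplog.records)

    def test_position_subset_one_based(self):
        x = amino_acid_frequencies(random_peptides(100, seed=33))
        res = pcc_aaf(x, x, positions=[2, 3, 9])
        assert res.positions == (2, 3, 9)
        assert res.mean == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        x = amino_acid_frequencies(random_peptides(10, length=9, seed=1))
        y = amino_acid_frequencies(random_peptides(10, length=10, seed=1))
        with pytest.raises(DataError):
            pcc_aaf(x, y)

    def test_sampling_consistency_toward_one(self):
        # non-uniform background so every position has structure for the
        # profiles to agree on as n grows (uniform rows have no variance)
        bg = np.arange(1, 21, dtype=float)
        bg /= bg.sum()
        spec = MotifSpec(anchors={2: ("L", 0.7), 9: ("V", 0.7)}, background=bg)
        means = []
        for n in (50, 500, 5000):
            vals = []
            for seed in range(10):
                a, _ = sample_motif_peptides(spec, n, 0.0, seed=100 + seed)
                b, _ = sample_motif_peptides(spec, n, 0.0, seed=200 + seed)
                vals.append(
                    pcc_aaf(amino_acid_frequencies(a), amino_acid_frequencies(b)).mean
                )
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.95
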