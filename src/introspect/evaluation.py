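"""Motif similarity between peptide sets: PCC of positional residue frequencies.

For two equal-length peptide sets, each position ``i`` yields two empirical
probability mass functions over the 20 residues, ``X_i`` and ``Y_i``.  Their
similarity at that position is the Pearson correlation computed over the 20
residue categories,

    PCC(X_i, Y_i) = cov(X_i, Y_i) / (sigma(X_i) * sigma(Y_i)),

and the summary statistic (``PCC_aaf``) is the mean over the requested
positions.  Positions follow the immunology P1..P9 convention (1-based); a
position where either pmf is exactly uniform has zero variance, an undefined
correlation, and is reported as missing and excluded from the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import N_RESIDUES, encode_peptides
from .errors import DataError, UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyProfile:
    """Position x residue empirical frequency matrix of a peptide set."""

    length: int
    pmf: np.ndarray  # (L, 20), rows sum to 1
    n: int

    def __post_init__(self) -> None:
        if self.pmf.shape != (self.length, N_RESIDUES):
            raise UsageError(f"pmf shape {self.pmf.shape} != ({self.length}, {N_RESIDUES})")
        if (self.pmf < 0).any() or not np.allclose(self.pmf.sum(axis=1), 1.0, atol=1e-12):
            raise UsageError("pmf rows must be probability mass functions")


def amino_acid_frequencies(peptides: Sequence[str]) -> FrequencyProfile:
    """Empirical per-position residue frequencies of an equal-length set."""
    if not peptides:
        raise DataError("amino_acid_frequencies: empty peptide list")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise DataError(f"amino_acid_frequencies: mixed lengths {sorted(lengths)}")
    length = lengths.pop()
    encoded = encode_peptides(list(peptides))
    pmf = np.empty((length, N_RESIDUES))
    for i in range(length):
        pmf[i] = np.bincount(encoded[:, i], minlength=N_RESIDUES)
    pmf /= len(peptides)
    return FrequencyProfile(length=length, pmf=pmf, n=len(peptides))


@dataclass(frozen=True)
class PccResult:
    positions: tuple[int, ...]  # 1-based
    per_position: np.ndarray  # NaN where undefined (zero variance)
    mean: float  # over defined positions only


def pcc_aaf(
    x: FrequencyProfile,
    y: FrequencyProfile,
    positions: Sequence[int] | str = "all",
) -> PccResult:
    """Per-position Pearson correlations of residue frequencies and their mean.

    ``positions`` is ``"all"`` or a list of 1-based positions (e.g. the
    anchors ``[2, 9]``).  Covariance and standard deviations are taken over
    the 20 residue categories (population convention; PCC is scale-free so
    the divisor choice cancels).
    """
    if x.length != y.length:
        raise DataError(f"profile lengths differ: {x.length} != {y.length}")
    if isinstance(positions, str):
        if positions != "all":
            raise UsageError(f"positions must be 'all' or a list, got {positions!r}")
        pos = tuple(range(1, x.length + 1))
    else:
        pos = tuple(int(p) for p in positions)
        bad = [p for p in pos if not 1 <= p <= x.length]
        if bad:
            raise UsageError(f"positions out of range 1..{x.length}: {bad}")
    values = np.empty(len(pos))
    for j, p in enumerate(pos):
        xi = x.pmf[p - 1]
        yi = y.pmf[p - 1]
        dx = xi - xi.mean()
        dy = yi - yi.mean()
        sx = np.sqrt((dx * dx).mean())
        sy = np.sqrt((dy * dy).mean())
        # pmf entries are O(1); below this the row is numerically uniform
        if sx <= 1e-12 or sy <= 1e-12:
            logger.warning("position %d has zero variance; PCC undefined, excluded", p)
            values[j] = np.nan
        else:
            values[j] = (dx * dy).mean() / (sx * sy)
    defined = values[~np.isnan(values)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return PccResult(positions=pos, per_position=values, mean=mean)
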