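"""Synthetic ground-truth data and a minimal two-round search simulation.

Three generators back the test bed and the examples:

* motif peptide sets — positions draw from a background residue
  distribution except at anchor positions (P2 and the C-terminus for HLA
  class I), where a fixed fraction of the mass (0.7 by default) sits on the
  anchor residue and the remainder is spread over the other residues in
  proportion to background;
* planted proteomes — each planted peptide embedded verbatim in a
  background protein, plus background filler proteins, so unspecific
  digestion provably recovers every planted peptide;
* a deliberately minimal target-decoy search simulation that reproduces
  the sensitivity mechanism of a targeted database: spectra matched
  against a larger database face more random-match competition (the number
  of competing candidates grows with database size), decoy scores rise,
  and fewer true peptides survive a fixed FDR cutoff.  It draws match
  scores from Gaussians rather than modelling spectra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Collection, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, N_RESIDUES
from .errors import DataError, UsageError
from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)


def _uniform_background() -> np.ndarray:
    return np.full(N_RESIDUES, 1.0 / N_RESIDUES)


@dataclass(frozen=True)
class MotifSpec:
    """A planted position-specific motif.

    ``anchors`` maps 1-based positions to ``(residue, probability_mass)``;
    at an anchor, the residue gets the stated mass and the remaining mass is
    spread over the other residues proportionally to the background.
    Non-anchor positions draw from the background directly.
    """

    length: int = 9
    anchors: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {2: ("L", 0.7), 9: ("V", 0.7)}
    )
    background: np.ndarray | None = None

    def position_distributions(self) -> np.ndarray:
        bg = self.background if self.background is not None else _uniform_background()
        bg = np.asarray(bg, dtype=float)
        dist = np.tile(bg, (self.length, 1))
        for pos, (residue, mass) in self.anchors.items():
            if not 1 <= pos <= self.length:
                raise UsageError(f"anchor position {pos} outside 1..{self.length}")
            if not 0.0 <= mass <= 1.0:
                raise UsageError(f"anchor mass must be in [0,1], got {mass}")
            a = AA_INDEX[residue]
            row = bg.copy()
            row[a] = 0.0
            row = row / row.sum() * (1.0 - mass)
            row[a] = mass
            dist[pos - 1] = row
        return dist


def sample_motif_peptides(
    spec: MotifSpec,
    n: int,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Draw motif peptides mixed with background peptides.

    ``round(n * (1 - noise_fraction))`` peptides are drawn position-wise
    from the motif; the remainder i.i.d. from the background.  Returns the
    peptides and their labels (``"motif"`` / ``"background"``).
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if not 0.0 <= noise_fraction <= 1.0:
        raise UsageError("noise_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_motif = round(n * (1.0 - noise_fraction))
    dist = spec.position_distributions()
    bg = spec.background if spec.background is not None else _uniform_background()
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    L = spec.length
    peptides: list[str] = []
    if n_motif:
        draws = np.stack(
            [rng.choice(N_RESIDUES, size=n_motif, p=dist[p]) for p in range(L)], axis=1
        )
        flat = letters[draws].tobytes().decode("ascii")
        peptides += [flat[i * L : (i + 1) * L] for i in range(n_motif)]
    n_bg = n - n_motif
    if n_bg:
        draws = rng.choice(N_RESIDUES, size=(n_bg, L), p=bg)
        flat = letters[draws].tobytes().decode("ascii")
        peptides += [flat[i * L : (i + 1) * L] for i in range(n_bg)]
    labels = ["motif"] * n_motif + ["background"] * n_bg
    return peptides, labels


def random_peptides(n: int, length: int = 9, seed: int = 0,
                    background: np.ndarray | None = None) -> list[str]:
    """n i.i.d. background peptides (vectorised; used for large spaces)."""
    rng = np.random.default_rng(seed)
    bg = background if background is not None else _uniform_background()
    draws = rng.choice(N_RESIDUES, size=(n, length), p=bg)
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    flat = letters[draws].tobytes().decode("ascii")
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def plant_proteome(
    planted_peptides: Sequence[str],
    n_filler_proteins: int,
    filler_length_range: tuple[int, int] = (200, 400),
    background: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Toy proteome with each planted peptide embedded in a host protein.

    Host proteins are background-sampled sequences with the peptide written
    verbatim at a random offset, so every planted peptide is guaranteed to
    be recovered by unspecific k-mer enumeration.
    """
    if not planted_peptides:
        raise DataError("plant_proteome: no planted peptides")
    lo, hi = filler_length_range
    if not 1 <= lo <= hi:
        raise UsageError(f"bad filler_length_range {filler_length_range}")
    rng = np.random.default_rng(seed)
    bg = background if background is not None else _uniform_background()
    letters = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

    def bg_sequence(length: int) -> str:
        return letters[rng.choice(N_RESIDUES, size=length, p=bg)].tobytes().decode("ascii")

    records: list[ProteinRecord] = []
    for i, pep in enumerate(planted_peptides):
        host_len = int(rng.integers(max(lo, len(pep)), hi + 1))
        host = bg_sequence(host_len)
        offset = int(rng.integers(0, host_len - len(pep) + 1))
        seq = host[:offset] + pep + host[offset + len(pep):]
        assert pep in seq
        records.append(ProteinRecord(id=f"HOST{i + 1:05d}", description=f"HOST{i + 1:05d} planted", sequence=seq))
    for i in range(n_filler_proteins):
        records.append(
            ProteinRecord(
                id=f"FILLER{i + 1:05d}",
                description=f"FILLER{i + 1:05d} background",
                sequence=bg_sequence(int(rng.integers(lo, hi + 1))),
            )
        )
    return records


@dataclass(frozen=True)
class SimConfig:
    """Score model for the minimal two-round search simulation.

    True-match scores are ``Normal(mu_true, sigma)``; random (incorrect)
    match scores are ``Normal(mu_random, sigma)``.  Each spectrum's
    competition grows with database size: the best random match is the
    maximum of ``ceil(candidate_rate * |db|)`` draws.
    """

    n_true_spectra: int = 2000
    mu_true: float = 2.0
    mu_random: float = 0.0
    sigma: float = 1.0
    fdr_level: float = 0.01
    candidate_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_true > self.mu_random:
            raise UsageError("mu_true must exceed mu_random")
        if not 0.0 < self.fdr_level < 0.5:
            raise UsageError("fdr_level must be in (0, 0.5)")


@dataclass(frozen=True)
class SimResult:
    ids_full: int
    ids_targeted: int
    n_true_spectra: int


def identifications_at_fdr(
    target_scores: np.ndarray, decoy_scores: np.ndarray, fdr_level: float
) -> int:
    """Largest accepted target count with (decoys >= cutoff)/(targets >= cutoff)
    at or below the FDR level, scanning target-score cutoffs."""
    ts = np.sort(target_scores)
    ds = np.sort(decoy_scores)
    # descending unique cutoffs at observed target scores
    best = 0
    for cutoff in ts[::-1]:
        n_t = ts.size - np.searchsorted(ts, cutoff, side="left")
        n_d = ds.size - np.searchsorted(ds, cutoff, side="left")
        if n_t and n_d / n_t <= fdr_level:
            best = max(best, int(n_t))
    return best


def _score_database(
    true_peptides: Sequence[str], db: Collection[str], sim: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum best target and decoy scores for one database.

    A fresh RNG seeded from ``sim.rng_seed`` is used per call, so the same
    database evaluated twice gives identical draws.
    """
    rng = np.random.default_rng(sim.rng_seed)
    n = sim.n_true_spectra
    k = max(1, math.ceil(sim.candidate_rate * len(db)))
    true_scores = rng.normal(sim.mu_true, sim.sigma, size=n)
    idx = rng.integers(0, len(true_peptides), size=n)
    present = np.array([true_peptides[i] in db for i in idx])
    n_miss = int((~present).sum())
    target = true_scores.copy()
    if n_miss:
        target[~present] = rng.normal(sim.mu_random, sim.sigma, size=(n_miss, k)).max(axis=1)
    decoy = rng.normal(sim.mu_random, sim.sigma, size=(n, k)).max(axis=1)
    return target, decoy


def simulate_two_round_gain(
    true_peptides: Sequence[str],
    full_db: Collection[str],
    targeted_db: Collection[str],
    sim: SimConfig = SimConfig(),
) -> SimResult:
    """Identifications at the FDR level for a full vs a targeted database.

    Each of ``n_true_spectra`` spectra corresponds to one true peptide
    (sampled with replacement).  If the peptide is absent from a database
    (a motif-filter miss) the spectrum's best match is random.  Decoys are
    a same-size reversed-peptide database scored with random-match draws.
    """
    missing_full = [p for p in true_peptides if p not in full_db]
    if missing_full:
        raise DataError(
            f"{len(missing_full)} true peptide(s) absent from the full database"
        )
    n_missing_targeted = sum(1 for p in true_peptides if p not in targeted_db)
    if n_missing_targeted:
        logger.info(
            "%d true peptide(s) absent from the targeted database (motif-filter misses)",
            n_missing_targeted,
        )
    t_full, d_full = _score_database(true_peptides, full_db, sim)
    t_targ, d_targ = _score_database(true_peptides, targeted_db, sim)
    return SimResult(
        ids_full=identifications_at_fdr(t_full, d_full, sim.fdr_level),
        ids_targeted=identifications_at_fdr(t_targ, d_targ, sim.fdr_level),
        n_true_spectra=sim.n_true_spectra,
    )


class SizedPeptideSet(Collection[str]):
    """A peptide 'database' defined by explicit members plus a nominal size.

    Large background databases only influence the simulation through their
    size and membership tests, so fillers need not be materialised.
    """

    def __init__(self, members: Collection[str], nominal_size: int) -> None:
        if nominal_size < len(set(members)):
            raise UsageError("nominal_size smaller than explicit member count")
        self._members = set(members)
        self._size = int(nominal_size)

    def __contains__(self, item: object) -> bool:
        return item in self._members

    def __iter__(self):
        return iter(self._members)

    def __len__(self) -> int:
        return self._size
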