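"""Motif deconvolution of first-round peptides by simulated-annealing Gibbs
sampling.

HLA class I samples usually mix ligands of several alleles, so the peptides
surviving the first-round 1% FDR filter carry a mixture of binding motifs.
This module partitions them into 1..6 clusters over a length-9 core
alignment (10/11-mers align to the core through up to two internal
deletions; terminal residues stay anchored at P1 and the C-terminal core
position), with an optional trash cluster absorbing outliers, and selects
the number of clusters by the maximum Kullback-Leibler objective.

Sampler
-------
State is a (cluster, alignment) pair per peptide.  One sweep visits every
peptide in seeded-random order, removes it from its cluster's counts, and
samples a new (cluster, alignment) with probability proportional to
``exp(score / T)`` where the score is the peptide's log2-odds fit to the
leave-one-out cluster frequency model (pseudocount-smoothed, shared with
the PSSM module).  A descending temperature schedule is followed by a
zero-temperature greedy sweep; ties in the greedy argmax break toward the
lowest candidate index (cluster-major, then alignment), which together with
the seeded RNG makes results fully deterministic.

Model selection
---------------
The objective of a solution is

    KLD = sum_c (n_c / N) * a_c * sum_{p,a} f~_cpa * log2(f~_cpa / B_a)
          - lambda * sum_{c<c'} max(0, corr(F_c, F_c'))

where ``f~`` are the pseudocount-smoothed cluster frequencies (the raw
plug-in KLD has an upward small-sample bias that rewards splitting
clusters), ``a_c = min(1, n_c / (sigma * motif_length))`` attenuates small
clusters and the penalty term is the Pearson correlation between
vectorised cluster frequency matrices, clipped at zero so only positive
motif similarity is penalised.  Ties between cluster numbers break toward
the smaller K (a K-cluster run that leaves clusters empty scores exactly
like the smaller effective K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import N_RESIDUES, encode_peptide
from .errors import DataError, UsageError
from .pssm import deletion_core_indices

logger = logging.getLogger(__name__)

TRASH = -1

_DEFAULT_TEMPERATURES = tuple(np.geomspace(1.5, 0.05, 20))


@dataclass(frozen=True)
class GibbsConfig:
    """Clustering parameters.

    The defaults are the standard parameterisation for HLA class I ligand
    deconvolution: clusters 1-6, motif length 9, at most two deletions and
    no insertions, five seeded restarts, inter-cluster similarity penalty
    0.8, small-cluster weight 5, trash cluster enabled with threshold 2,
    and ten sweeps per sequence per temperature step.

    ``trash_threshold`` is interpreted on the scale given by
    ``trash_score_scale``: ``"total"`` (default) compares the peptide's
    summed log2-odds fit over the 9 core positions, ``"per_position"``
    compares the per-position average.

    ``omega`` is the sampler's pseudocount weight.  It is deliberately
    heavier (1.0) than the 0.1 used for the final scoring matrices: with a
    light pseudocount the per-position log-odds noise of a ~100-peptide
    cluster rivals a two-anchor motif signal, and the chain freezes in
    mixed states where each cluster has memorised its members' non-anchor
    residues.  Heavier smoothing compresses that noise while leaving the
    anchor signal dominant.
    """

    cluster_range: tuple[int, int] = (1, 6)
    motif_length: int = 9
    max_deletions: int = 2
    max_insertions: int = 0
    n_seeds: int = 5
    inter_cluster_penalty: float = 0.8  # lambda
    small_cluster_weight: float = 5.0  # sigma
    use_trash: bool = True
    trash_threshold: float = 2.0
    trash_score_scale: str = "total"
    iters_per_seq_per_temp: int = 10
    temperatures: tuple[float, ...] = _DEFAULT_TEMPERATURES
    omega: float = 1.0
    #: pseudocount weight for the trash rule's log2-odds scores; matches the
    #: default PSSM training weight so the rule operates on the same scale
    #: as the final motif models rather than the sampler's smoothed search
    #: models
    scoring_omega: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cluster_range
        if not (1 <= lo <= hi):
            raise UsageError(f"invalid cluster_range {self.cluster_range}")
        if self.max_insertions != 0:
            raise UsageError("insertions are not supported (max_insertions must be 0)")
        if self.motif_length < 1 or self.max_deletions < 0:
            raise UsageError("motif_length >= 1 and max_deletions >= 0 required")
        if self.trash_score_scale not in ("total", "per_position"):
            raise UsageError(f"unknown trash_score_scale {self.trash_score_scale!r}")
        if not all(t > 0 for t in self.temperatures) or list(self.temperatures) != sorted(
            self.temperatures, reverse=True
        ):
            raise UsageError("temperatures must be a descending positive schedule")

    @property
    def alignable_lengths(self) -> range:
        return range(self.motif_length, self.motif_length + self.max_deletions + 1)


@dataclass(frozen=True)
class Alignment:
    """Internal-deletion alignment of a peptide onto the motif core.

    ``deletion_positions`` are sorted 0-based peptide indices excluded from
    the core; the first and last peptide residues are never deleted, so the
    P1 and C-terminal anchors are preserved.
    """

    deletion_positions: tuple[int, ...] = ()

    def core_indices(self, peptide_length: int) -> np.ndarray:
        return np.delete(np.arange(peptide_length, dtype=np.intp), list(self.deletion_positions))


@dataclass
class ClusterSolution:
    """Best sampler run for one cluster number K."""

    K: int
    peptides: tuple[str, ...]
    assignment: np.ndarray  # per-peptide cluster 0..K-1, or TRASH (-1)
    alignments: list[Alignment | None]  # None for trash peptides
    kld: float
    per_cluster_kld: list[float]
    cluster_frequency_matrices: list[np.ndarray]  # K x (motif_length, 20)

    @property
    def cluster_sizes(self) -> list[int]:
        return [int((self.assignment == c).sum()) for c in range(self.K)]

    @property
    def n_trash(self) -> int:
        return int((self.assignment == TRASH).sum())


@dataclass
class ClusteringResult:
    solutions: dict[int, ClusterSolution]
    selected_K: int

    @property
    def selected(self) -> ClusterSolution:
        return self.solutions[self.selected_K]


@dataclass
class RetainedPeptides:
    """Non-trash peptides of the selected solution, grouped by cluster."""

    groups: dict[int, list[tuple[str, Alignment]]]
    trash: list[str]

    @property
    def n_trash(self) -> int:
        return len(self.trash)


def cluster_peptides(
    peptides: Sequence[str],
    config: GibbsConfig = GibbsConfig(),
    background: np.ndarray | None = None,
) -> ClusteringResult:
    """Partition peptides into motif clusters for each K and select K.

    ``background`` is the residue frequency vector used by both the
    sampler's log-odds fits and the KLD objective; defaults to uniform.
    """
    peptides = list(peptides)
    m = config.motif_length
    if len(peptides) < m:
        raise DataError(
            f"need at least {m} peptides to train a length-{m} motif, got {len(peptides)}"
        )
    bad = [p for p in peptides if len(p) not in config.alignable_lengths]
    if bad:
        raise DataError(
            f"{len(bad)} peptide(s) not alignable (lengths must be in "
            f"{config.alignable_lengths.start}-{config.alignable_lengths.stop - 1}), "
            f"e.g. {bad[0]!r}"
        )
    if background is None:
        background = np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    background = np.asarray(background, dtype=float)

    # precompute per-peptide candidate cores: (n_alignments, m) residue codes
    keep_cache: dict[int, np.ndarray] = {
        L: deletion_core_indices(L, m) for L in sorted({len(p) for p in peptides})
    }
    codes = [encode_peptide(p) for p in peptides]
    cores = [c[keep_cache[len(c)]] for c in codes]

    lo, hi = config.cluster_range
    solutions: dict[int, ClusterSolution] = {}
    for K in range(lo, hi + 1):
        best: ClusterSolution | None = None
        for seed_idx in range(config.n_seeds):
            sol = _run_sampler(peptides, cores, keep_cache, K, seed_idx, config, background)
            if best is None or sol.kld > best.kld:
                best = sol
        assert best is not None
        solutions[K] = best
        logger.info(
            "K=%d: KLD=%.4f sizes=%s trash=%d",
            K,
            best.kld,
            best.cluster_sizes,
            best.n_trash,
        )
    selected_K = lo
    for K in range(lo, hi + 1):
        if solutions[K].kld > solutions[selected_K].kld:
            selected_K = K
    return ClusteringResult(solutions=solutions, selected_K=selected_K)


def retained_peptides(result: ClusteringResult) -> RetainedPeptides:
    """Peptides of the highest-KLD solution, grouped by cluster, trash apart."""
    sol = result.selected
    groups: dict[int, list[tuple[str, Alignment]]] = {c: [] for c in range(sol.K)}
    trash: list[str] = []
    for pep, c, aln in zip(sol.peptides, sol.assignment, sol.alignments):
        if c == TRASH:
            trash.append(pep)
        else:
            assert aln is not None
            groups[int(c)].append((pep, aln))
    return RetainedPeptides(groups=groups, trash=trash)


# ---------------------------------------------------------------------------
# sampler internals


class _State:
    """Mutable sampler state with cached per-cluster log-odds matrices."""

    def __init__(self, K: int, m: int, background: np.ndarray, omega: float) -> None:
        self.K = K
        self.m = m
        self.B = background
        self.omega = omega
        self.counts = np.zeros((K, m, N_RESIDUES))
        self.sizes = np.zeros(K, dtype=np.int64)
        self.logodds = np.zeros((K, m, N_RESIDUES))
        self._pos = np.arange(m)

    def refresh(self, c: int) -> None:
        n = self.sizes[c]
        if n == 0:
            self.logodds[c] = 0.0
            return
        f = self.counts[c] / n
        smoothed = (f + self.omega * self.B) / (1.0 + self.omega)
        self.logodds[c] = np.log2(smoothed / self.B)

    def add(self, c: int, core: np.ndarray) -> None:
        self.counts[c, self._pos, core] += 1
        self.sizes[c] += 1
        self.refresh(c)

    def remove(self, c: int, core: np.ndarray) -> None:
        self.counts[c, self._pos, core] -= 1
        self.sizes[c] -= 1
        self.refresh(c)


def _run_sampler(
    peptides: list[str],
    cores: list[np.ndarray],
    keep_cache: dict[int, np.ndarray],
    K: int,
    seed_idx: int,
    config: GibbsConfig,
    background: np.ndarray,
) -> ClusterSolution:
    n = len(peptides)
    m = config.motif_length
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, K, seed_idx]))
    state = _State(K, m, background, config.omega)
    pos = np.arange(m)

    assign = rng.integers(0, K, size=n)
    align_choice = np.array([rng.integers(0, len(c)) for c in cores], dtype=np.intp)
    for j in range(n):
        state.add(int(assign[j]), cores[j][align_choice[j]])

    # nothing to resample when there is a single candidate state per peptide
    trivial = K == 1 and all(len(c) == 1 for c in cores)

    def visit(j: int, temperature: float | None) -> None:
        c_old = int(assign[j])
        state.remove(c_old, cores[j][align_choice[j]])
        scores = state.logodds[:, pos, cores[j]].sum(axis=2)  # (K, n_align)
        if temperature is None:  # greedy: ties -> lowest flat index
            flat = int(np.argmax(scores))
        else:
            z = (scores - scores.max()) / temperature
            w = np.exp(z).ravel()
            cw = np.cumsum(w)
            flat = min(int(np.searchsorted(cw, rng.random() * cw[-1], side="right")), w.size - 1)
        c_new, a_new = divmod(flat, scores.shape[1])
        assign[j] = c_new
        align_choice[j] = a_new
        state.add(int(c_new), cores[j][a_new])

    if not trivial:
        for temperature in config.temperatures:
            for _ in range(config.iters_per_seq_per_temp):
                for j in rng.permutation(n):
                    visit(int(j), temperature)
        # zero-temperature polish, iterated to a fixed point
        for _ in range(20):
            before = (assign.copy(), align_choice.copy())
            for j in range(n):
                visit(j, None)
            if (assign == before[0]).all() and (align_choice == before[1]).all():
                break

    # trash assignment: full-count models at the PSSM scoring pseudocount,
    # best alignment against the peptide's own cluster
    if config.use_trash:
        divisor = m if config.trash_score_scale == "per_position" else 1
        trash_logodds = np.zeros_like(state.logodds)
        for c in range(K):
            if state.sizes[c] > 0:
                f = state.counts[c] / state.sizes[c]
                smoothed = (f + config.scoring_omega * background) / (1.0 + config.scoring_omega)
                trash_logodds[c] = np.log2(smoothed / background)
        for j in range(n):
            c = int(assign[j])
            s = trash_logodds[c, pos, cores[j]].sum(axis=1).max()
            if s / divisor < config.trash_threshold:
                state.remove(c, cores[j][align_choice[j]])
                assign[j] = TRASH

    kld, per_cluster, freqs = _objective(state, config)
    alignments: list[Alignment | None] = []
    for j in range(n):
        if assign[j] == TRASH:
            alignments.append(None)
        else:
            keep = keep_cache[len(peptides[j])][align_choice[j]]
            dels = tuple(sorted(set(range(len(peptides[j]))) - set(keep.tolist())))
            alignments.append(Alignment(deletion_positions=dels))
    return ClusterSolution(
        K=K,
        peptides=tuple(peptides),
        assignment=assign.copy(),
        alignments=alignments,
        kld=kld,
        per_cluster_kld=per_cluster,
        cluster_frequency_matrices=freqs,
    )


def _objective(state: _State, config: GibbsConfig) -> tuple[float, list[float], list[np.ndarray]]:
    """KLD objective of the current partition (trash already excluded)."""
    m = config.motif_length
    total_n = int(state.sizes.sum())
    per_cluster: list[float] = []
    freqs: list[np.ndarray] = []
    weighted = 0.0
    for c in range(state.K):
        n_c = int(state.sizes[c])
        if n_c == 0:
            per_cluster.append(0.0)
            freqs.append(np.zeros((m, N_RESIDUES)))
            continue
        f = state.counts[c] / n_c
        # pseudocount-smoothed KLD: the raw plug-in estimate carries a
        # ~(19*m)/(2*ln2*n) upward bias that rewards splitting clusters
        smoothed = (f + config.omega * state.B) / (1.0 + config.omega)
        kld_c = float((smoothed * np.log2(smoothed / state.B)).sum())
        per_cluster.append(kld_c)
        freqs.append(f)
        attenuation = min(1.0, n_c / (config.small_cluster_weight * m))
        if total_n:
            weighted += (n_c / total_n) * attenuation * kld_c
    penalty = 0.0
    occupied = [c for c in range(state.K) if state.sizes[c] > 0]
    for i, c in enumerate(occupied):
        for cp in occupied[i + 1 :]:
            x = freqs[c].ravel()
            y = freqs[cp].ravel()
            dx = x - x.mean()
            dy = y - y.mean()
            denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
            if denom > 0:
                penalty += max(0.0, float((dx * dy).sum() / denom))
    return weighted - config.inter_cluster_penalty * penalty, per_cluster, freqs


def solution_report(sol: ClusterSolution) -> str:
    """Plain-text per-cluster summary: size, KLD, consensus sequence."""
    from .alphabet import AMINO_ACIDS

    lines = [f"K={sol.K}\tKLD={sol.kld:.4f}\ttrash={sol.n_trash}"]
    for c in range(sol.K):
        size = sol.cluster_sizes[c]
        freq = sol.cluster_frequency_matrices[c]
        consensus = "".join(AMINO_ACIDS[i] for i in freq.argmax(axis=1)) if size else "-"
        lines.append(
            f"cluster {c + 1}\tsize={size}\tKLD={sol.per_cluster_kld[c]:.4f}\t"
            f"consensus={consensus}"
        )
    return "\n".join(lines)
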