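"""Position-specific scoring matrices: training, scoring, k-mer filtering.

The motif model for a cluster of equal-length ligands is a matrix
``P[i, a]`` over positions ``i`` and the 20 residues ``a``.  Training
counts give per-position frequencies ``F[i, a]``; a pseudocount weight
``omega`` smooths them against the background residue distribution
``B[a]`` of the protein database:

    f~[i, a] = (F[i, a] + omega * B[a]) / (1 + omega)

Under the default ``log_odds`` form, ``P[i, a] = log2(f~[i, a] / B[a])``,
so a peptide drawn residue-wise from the background has expected motif
score ~0 and the filter threshold (0.3 by default, strict) sits just above
background.  The literal ``as_printed`` form,
``P[i, a] = log2(F[i, a] + omega * B[a])``, is kept as an option; being a
sum of log-frequencies it is negative for every peptide.

The motif score of a peptide is the *sum* of its per-position entries (no
length normalisation).  Motif models are length-specific; lengths without
enough training peptides are scored through a cluster's 9-mer core matrix
by maximising over legal internal-deletion alignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, N_RESIDUES, encode_peptide, encode_peptides, encode_protein
from .errors import DataError, UsageError
from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

#: every background frequency is floored here and renormalised, so log-odds
#: scores stay finite even for degenerate toy proteomes
BACKGROUND_FLOOR = 1e-6

LOG_ODDS = "log_odds"
AS_PRINTED = "as_printed"


def background_frequencies(proteins: Sequence[ProteinRecord]) -> np.ndarray:
    """Residue frequencies of a protein database (the ``B_a`` vector).

    Ambiguity codes are excluded from the counts.  Every entry is floored
    at ``BACKGROUND_FLOOR`` and the vector renormalised to sum to 1.
    """
    if not proteins:
        raise DataError("background_frequencies: empty protein list")
    counts = np.zeros(N_RESIDUES, dtype=np.int64)
    for prot in proteins:
        codes = encode_protein(prot.sequence.upper())
        codes = codes[codes != 255]
        counts += np.bincount(codes, minlength=N_RESIDUES)
    total = counts.sum()
    if total == 0:
        raise DataError("background_frequencies: no standard residues in input")
    freqs = counts / total
    freqs = np.maximum(freqs, BACKGROUND_FLOOR)
    return freqs / freqs.sum()


@dataclass(frozen=True)
class Pssm:
    """A trained position-specific scoring matrix for one (cluster, length)."""

    cluster_id: int
    length: int
    matrix: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    omega: float
    n_train: int
    scoring_form: str = LOG_ODDS

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.length, N_RESIDUES):
            raise UsageError(
                f"matrix shape {self.matrix.shape} != ({self.length}, {N_RESIDUES})"
            )
        if not np.isfinite(self.matrix).all():
            raise UsageError("PSSM matrix contains non-finite entries")


@dataclass(frozen=True)
class TrainingCounts:
    counts: np.ndarray  # (L, 20) integers
    frequencies: np.ndarray  # (L, 20) rows summing to 1


def count_residues(encoded: np.ndarray) -> TrainingCounts:
    """Per-position residue counts and frequencies of an (n, L) code matrix."""
    n, length = encoded.shape
    counts = np.zeros((length, N_RESIDUES), dtype=np.int64)
    for i in range(length):
        counts[i] = np.bincount(encoded[:, i], minlength=N_RESIDUES)
    return TrainingCounts(counts=counts, frequencies=counts / n)


def pseudocount_frequencies(
    frequencies: np.ndarray, background: np.ndarray, omega: float
) -> np.ndarray:
    """Smoothed frequencies ``(F + omega*B) / (1 + omega)``."""
    return (frequencies + omega * background) / (1.0 + omega)


def train_pssm(
    peptides: Sequence[str],
    background: np.ndarray,
    omega: float = 0.1,
    scoring_form: str = LOG_ODDS,
    cluster_id: int = 0,
    expected_length: int | None = None,
) -> Pssm:
    """Train a PSSM from equal-length peptides against a background."""
    if not peptides:
        raise DataError("train_pssm: no training peptides")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise DataError(f"train_pssm: mixed peptide lengths {sorted(lengths)}")
    length = lengths.pop()
    if expected_length is not None and length != expected_length:
        raise DataError(f"train_pssm: length {length} != expected {expected_length}")
    if omega <= 0:
        raise UsageError("omega must be > 0 (pseudocounts keep every log finite)")
    encoded = encode_peptides(list(peptides))
    tc = count_residues(encoded)
    matrix = matrix_from_frequencies(tc.frequencies, background, omega, scoring_form)
    return Pssm(
        cluster_id=cluster_id,
        length=length,
        matrix=matrix,
        background=np.asarray(background, dtype=float),
        omega=omega,
        n_train=len(peptides),
        scoring_form=scoring_form,
    )


def matrix_from_frequencies(
    frequencies: np.ndarray,
    background: np.ndarray,
    omega: float,
    scoring_form: str = LOG_ODDS,
) -> np.ndarray:
    smoothed = pseudocount_frequencies(frequencies, background, omega)
    if scoring_form == LOG_ODDS:
        return np.log2(smoothed / background)
    if scoring_form == AS_PRINTED:
        return np.log2(frequencies + omega * background)
    raise UsageError(f"unknown scoring_form {scoring_form!r}")


def score_peptide(pssm: Pssm, peptide: str) -> float:
    """Motif score: the sum of matrix entries at each peptide position."""
    if len(peptide) != pssm.length:
        raise DataError(
            f"peptide length {len(peptide)} != PSSM length {pssm.length}"
        )
    codes = encode_peptide(peptide)
    return float(pssm.matrix[np.arange(pssm.length), codes].sum())


def score_peptides(pssm: Pssm, encoded: np.ndarray) -> np.ndarray:
    """Vectorised motif scores for an (n, L) encoded peptide matrix."""
    if encoded.shape[1] != pssm.length:
        raise DataError("encoded peptide length mismatch")
    return pssm.matrix[np.arange(pssm.length), encoded].sum(axis=1)


def deletion_core_indices(length: int, core: int, terminal_anchors: bool = True) -> np.ndarray:
    """All kept-position index vectors aligning a *length*-mer to a *core*-mer.

    Deletions are internal: the first and last residues always occupy the
    first and last core positions (P1 and the C-terminal anchor).  Returned
    array has shape (n_alignments, core); alignments are ordered by their
    sorted deletion-position tuples.
    """
    n_del = length - core
    if n_del < 0:
        raise UsageError(f"cannot align a {length}-mer to a longer {core}-mer core")
    if n_del == 0:
        return np.arange(core, dtype=np.intp)[None, :]
    positions = range(1, length - 1) if terminal_anchors else range(length)
    combos = list(itertools.combinations(positions, n_del))
    keep = np.empty((len(combos), core), dtype=np.intp)
    full = np.arange(length, dtype=np.intp)
    for r, dels in enumerate(combos):
        keep[r] = np.delete(full, list(dels))
    return keep


def score_with_deletions(pssm: Pssm, peptide: str, max_deletions: int = 2) -> float:
    """Best core-alignment score of a longer peptide against a core PSSM."""
    n_del = len(peptide) - pssm.length
    if n_del < 0 or n_del > max_deletions:
        raise DataError(
            f"{len(peptide)}-mer not alignable to {pssm.length}-mer core "
            f"with <= {max_deletions} deletions"
        )
    codes = encode_peptide(peptide)
    keep = deletion_core_indices(len(peptide), pssm.length)
    return float(pssm.matrix[np.arange(pssm.length), codes[keep]].sum(axis=1).max())


@dataclass(frozen=True)
class FilterRecord:
    """Best-scoring model for a peptide that passed the motif filter."""

    best_score: float
    best_model: str
    via_core: bool = False


def model_name(pssm: Pssm, core: bool = False) -> str:
    tag = "core" if core else f"L{pssm.length}"
    return f"c{pssm.cluster_id}_{tag}"


def filter_kmers(
    kmers_by_length: Mapping[int, Sequence[str]],
    pssms: Sequence[Pssm],
    threshold: float = 0.3,
    core_fallback: Sequence[Pssm] = (),
    max_deletions: int = 2,
    fallback_lengths: "set[int] | None" = None,
) -> dict[str, FilterRecord]:
    """Filter the k-mer space at the motif-score threshold (strict ``>``).

    A peptide passes iff its best score over all same-length PSSMs exceeds
    *threshold*.  Lengths with no exact-length model are scored through the
    ``core_fallback`` matrices (best over legal internal-deletion
    alignments) and flagged ``via_core``; if no fallback applies either,
    the length is dropped with a logged warning.

    ``fallback_lengths`` restricts which lengths may use the core fallback
    (``None`` allows all).  The database builder passes the lengths actually
    observed among the first-round hits: a length with *no* identified
    ligands has no evidence of being presented, and scoring it as the best
    of many core alignments admits far more background k-mers than a
    directly trained matrix would.
    """
    by_length: dict[int, list[Pssm]] = {}
    for p in pssms:
        by_length.setdefault(p.length, []).append(p)

    passing: dict[str, FilterRecord] = {}
    any_scored = False
    for length, peptides in sorted(kmers_by_length.items()):
        if not len(peptides):
            continue
        peptides = list(peptides)
        encoded = encode_peptides(peptides)
        models = by_length.get(length)
        if models:
            any_scored = True
            best = np.full(len(peptides), -np.inf)
            best_idx = np.zeros(len(peptides), dtype=np.intp)
            for mi, m in enumerate(models):
                s = score_peptides(m, encoded)
                upd = s > best
                best[upd] = s[upd]
                best_idx[upd] = mi
            names = [model_name(m) for m in models]
            via_core = False
        else:
            allowed = fallback_lengths is None or length in fallback_lengths
            cores = (
                [c for c in core_fallback if 0 <= length - c.length <= max_deletions]
                if allowed
                else []
            )
            if not cores:
                logger.warning(
                    "no PSSM for length %d and no usable core model: dropping %d k-mers",
                    length,
                    len(peptides),
                )
                continue
            any_scored = True
            best = np.full(len(peptides), -np.inf)
            best_idx = np.zeros(len(peptides), dtype=np.intp)
            for mi, c in enumerate(cores):
                keep = deletion_core_indices(length, c.length)
                # (n_pep, n_align, core) gather, max over alignments
                s = c.matrix[np.arange(c.length), encoded[:, keep]].sum(axis=2).max(axis=1)
                upd = s > best
                best[upd] = s[upd]
                best_idx[upd] = mi
            names = [model_name(c, core=True) for c in cores]
            via_core = True
        mask = best > threshold
        for j in np.nonzero(mask)[0]:
            passing[peptides[j]] = FilterRecord(
                best_score=float(best[j]),
                best_model=names[best_idx[j]],
                via_core=via_core,
            )
    if not any_scored:
        raise DataError("filter_kmers: no PSSM matches any k-mer length")
    return passing


# ---------------------------------------------------------------------------
# serialization: tab-separated matrix, bit-exact round trip ('%.17g' floats)

def write_pssm(pssm: Pssm, path: str | Path) -> None:
    """Serialise a PSSM as a tab-separated matrix file."""
    with open(path, "w") as fh:
        fh.write(
            f"# pssm\tcluster_id={pssm.cluster_id}\tlength={pssm.length}"
            f"\tomega={pssm.omega!r}\tn_train={pssm.n_train}\tform={pssm.scoring_form}\n"
        )
        fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
        fh.write("bg\t" + "\t".join(f"{x:.17g}" for x in pssm.background) + "\n")
        for i in range(pssm.length):
            fh.write(f"{i + 1}\t" + "\t".join(f"{x:.17g}" for x in pssm.matrix[i]) + "\n")


def read_pssm(path: str | Path) -> Pssm:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# pssm"):
        raise DataError(f"{path}: not a PSSM file")
    meta = dict(kv.split("=", 1) for kv in lines[0].split("\t")[1:])
    header = lines[1].split("\t")
    if header[0] != "pos" or "".join(header[1:]) != AMINO_ACIDS:
        raise DataError(f"{path}: unexpected residue column order")
    bg_fields = lines[2].split("\t")
    if bg_fields[0] != "bg":
        raise DataError(f"{path}: missing background row")
    background = np.array([float(x) for x in bg_fields[1:]])
    length = int(meta["length"])
    matrix = np.array(
        [[float(x) for x in lines[3 + i].split("\t")[1:]] for i in range(length)]
    )
    return Pssm(
        cluster_id=int(meta["cluster_id"]),
        length=length,
        matrix=matrix,
        background=background,
        omega=float(meta["omega"]),
        n_train=int(meta["n_train"]),
        scoring_form=meta["form"],
    )
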