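"""Input/output: proteome FASTA, first-round peptide tables, peptide FASTA.

The first-round identifications come either from Percolator's peptide-level
``pout.tab`` output or from a plain one-peptide-per-line list.  Percolator
rows are ragged — a peptide mapping to several proteins carries extra
tab-separated fields past the header — so the dialect is parsed by hand.

Peptide sequences are reduced to bare residue strings before any downstream
use: flanking-residue notation (``K.AIFQSSMTK.V``), bracketed or
parenthesised mass tags and lowercase modification tags are all stripped.
The pipeline clusters and scores unmodified sequences only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

from .alphabet import AMBIGUOUS_CODES, AMINO_ACIDS, is_standard_peptide
from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .builder import TargetedDatabase

logger = logging.getLogger(__name__)

_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | AMBIGUOUS_CODES


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: id (header up to first whitespace), description,
    uppercase sequence with any trailing stop ``*`` removed."""

    id: str
    description: str
    sequence: str
    is_contaminant: bool = False


@dataclass(frozen=True)
class PeptideHit:
    """One first-round identified peptide (peptide-level, not PSM-level)."""

    sequence: str
    length: int
    q_value: float | None = None
    search_score: float | None = None
    protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("length field must equal len(sequence)")


def read_protein_fasta(path: str | Path, contaminant: bool = False) -> list[ProteinRecord]:
    """Read a protein database in FASTA format.

    Sequences are uppercased and a single trailing ``*`` (stop codon) is
    stripped.  Ambiguity codes (B, J, O, U, X, Z) are legal in proteins;
    anything else raises :class:`DataError`.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise DataError(f"record {entry.id!r}: empty sequence")
        bad = set(seq) - _PROTEIN_ALPHABET
        if bad:
            raise DataError(
                f"record {entry.id!r}: illegal character(s) {sorted(bad)} in sequence"
            )
        seen[entry.id] = seen.get(entry.id, 0) + 1
        records.append(
            ProteinRecord(
                id=entry.id,
                description=entry.description,
                sequence=seq,
                is_contaminant=contaminant,
            )
        )
    if not records:
        raise DataError(f"{path}: no sequences")
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise DataError(f"{path}: duplicate FASTA ids {dupes}")
    return records


_FLANK_RE = re.compile(r"^(?:[A-Z*-])\.(.*)\.(?:[A-Z*-])$")
_TAG_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def strip_modifications(peptide: str) -> str:
    """Reduce a search-engine peptide string to bare uppercase residues.

    Removes ``X.PEPTIDE.X`` flanking-residue notation, ``[...]``/``(...)``
    mass-tag groups, lowercase modification tags and any remaining
    non-letter characters.  Idempotent on already-bare sequences.
    """
    s = peptide.strip()
    m = _FLANK_RE.match(s)
    if m:
        s = m.group(1)
    s = _TAG_RE.sub("", s)
    return "".join(c for c in s if c.isalpha() and c.isupper())


def read_peptide_hits(
    path: str | Path,
    dialect: str = "percolator_pout",
    q_threshold: float = 0.01,
    drop_contaminants: bool = False,
    contaminant_ids: Iterable[str] = (),
) -> list[PeptideHit]:
    """Read first-round peptide identifications.

    Parameters
    ----------
    dialect
        ``"percolator_pout"`` (tab-separated, header-driven, needs a peptide
        and a q-value column) or ``"plain_list"`` (one peptide per line,
        ``#`` comments).
    q_threshold
        Hits with q-value above this are removed (peptide-level FDR filter).
    drop_contaminants
        Remove hits whose *entire* protein assignment lies within
        ``contaminant_ids``.

    Duplicate sequences collapse to one hit keeping the minimum q-value and
    the union of protein ids.  Hits containing ambiguity codes are rejected
    with a logged warning count.
    """
    if dialect == "percolator_pout":
        raw = _parse_percolator(path)
    elif dialect == "plain_list":
        raw = _parse_plain_list(path)
    else:
        raise DataError(f"unknown dialect {dialect!r}")

    contaminant_ids = set(contaminant_ids)
    best: dict[str, PeptideHit] = {}
    n_rejected = 0
    n_q_filtered = 0
    n_contaminant = 0
    for seq, q, score, prots in raw:
        bare = strip_modifications(seq)
        if not is_standard_peptide(bare):
            n_rejected += 1
            continue
        if q is not None and q > q_threshold:
            n_q_filtered += 1
            continue
        if drop_contaminants and prots and set(prots) <= contaminant_ids:
            n_contaminant += 1
            continue
        prev = best.get(bare)
        if prev is None:
            best[bare] = PeptideHit(bare, len(bare), q, score, tuple(prots))
        else:
            keep_new = _q_key(q) < _q_key(prev.q_value)
            merged_prots = tuple(dict.fromkeys(prev.protein_ids + tuple(prots)))
            src = (q, score) if keep_new else (prev.q_value, prev.search_score)
            best[bare] = PeptideHit(bare, len(bare), src[0], src[1], merged_prots)
    if n_rejected:
        logger.warning("%d hit(s) rejected: ambiguity codes or empty after stripping", n_rejected)
    if n_contaminant:
        logger.info("%d contaminant-only hit(s) removed", n_contaminant)
    logger.info(
        "read %d unique peptide hits (%d removed at q>%g)", len(best), n_q_filtered, q_threshold
    )
    if not best:
        raise DataError(f"{path}: empty first-round set after filtering")
    return list(best.values())


def _q_key(q: float | None) -> float:
    return float("inf") if q is None else q


def _parse_percolator(path: str | Path):
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split("\t")]
    lower = [h.lower() for h in header]

    def find(*names: str) -> int | None:
        for n in names:
            if n in lower:
                return lower.index(n)
        return None

    pep_col = find("peptide")
    q_col = find("q-value", "qvalue", "q_value")
    if pep_col is None:
        raise DataError(f"{path}: missing required column 'peptide'")
    if q_col is None:
        raise DataError(f"{path}: missing required column 'q-value'")
    score_col = find("score")
    prot_col = find("proteinids", "proteins", "protein")

    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        seq = fields[pep_col]
        q = float(fields[q_col])
        score = float(fields[score_col]) if score_col is not None else None
        # proteins occupy the proteinIds column and any ragged extras past it
        if prot_col is not None and prot_col < len(fields):
            prots = [p for p in fields[prot_col:] if p.strip()]
        else:
            prots = []
        out.append((seq, q, score, prots))
    return out


def _parse_plain_list(path: str | Path):
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.split("#", 1)[0].strip()
        if s:
            out.append((s, None, None, []))
    if not out:
        raise DataError(f"{path}: empty file")
    return out


def write_peptide_fasta(db: "TargetedDatabase", path: str | Path) -> int:
    """Write a targeted database as a peptide-per-entry FASTA.

    Headers carry a stable serial, the provenance tags joined by ``;`` in
    sorted order, and the best motif score (``NA`` when the peptide was
    injected without a score).  Peptides are written in lexicographic order,
    so identical databases produce byte-identical files.
    """
    peptides = db.peptides
    if not peptides:
        raise DataError("cannot write an empty targeted database")
    n = 0
    with open(path, "w") as fh:
        for serial, seq in enumerate(sorted(peptides), start=1):
            entry = peptides[seq]
            prov = ";".join(sorted(entry.provenance))
            score = "NA" if entry.best_score is None else f"{entry.best_score:.4f}"
            fh.write(f">pep{serial:06d}|{prov}|score={score}\n{seq}\n")
            n += 1
    logger.info("wrote %d peptides to %s", n, path)
    return n
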