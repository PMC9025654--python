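"""Unspecific in-silico digestion: every k-mer window of a protein database.

HLA class I ligands are produced by proteasomal cleavage with no enzymatic
motif, so the search space is *all* substrings of the configured lengths
(9–11 by default) — roughly 1e8 windows for a whole human proteome.  The
enumerator therefore streams windows and stores only the deduplicated
peptide set, keeping a single representative source protein per peptide
unless full provenance is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import encode_protein
from .errors import DataError, UsageError
from .io_formats import ProteinRecord


@dataclass(frozen=True)
class DigestConfig:
    """Window lengths for unspecific digestion (inclusive range)."""

    min_length: int = 9
    max_length: int = 11
    skip_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not (7 <= self.min_length <= self.max_length <= 15):
            raise UsageError(
                f"peptide length range must satisfy 7 <= min <= max <= 15, "
                f"got {self.min_length}-{self.max_length}"
            )

    @property
    def lengths(self) -> range:
        return range(self.min_length, self.max_length + 1)


@dataclass
class DigestResult:
    """Deduplicated k-mer space with per-length pre-dedup window counts.

    ``sources`` maps each unique peptide to its representative source
    protein id (or the full tuple of source ids when ``track_all_sources``).
    """

    sources: dict[str, object]
    window_counts: dict[int, int] = field(default_factory=dict)

    @property
    def peptides(self) -> set[str]:
        return set(self.sources)

    def __len__(self) -> int:
        return len(self.sources)

    def by_length(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pep in self.sources:
            out.setdefault(len(pep), []).append(pep)
        return out


def enumerate_kmers(
    proteins: list[ProteinRecord],
    config: DigestConfig = DigestConfig(),
    track_all_sources: bool = False,
) -> DigestResult:
    """Enumerate all unique k-mers of the configured lengths.

    Windows containing ambiguity codes are skipped when
    ``config.skip_ambiguous`` (a 20-residue scoring matrix cannot score
    them).  ``window_counts[k]`` is the number of non-skipped windows
    *before* deduplication, so the counting identity
    ``window_counts[k] == sum(max(0, n_i - k + 1)) - skipped`` holds exactly.
    """
    if not proteins:
        raise DataError("enumerate_kmers: empty protein list")
    sources: dict[str, object] = {}
    window_counts = {k: 0 for k in config.lengths}
    for prot in proteins:
        seq = prot.sequence.upper()
        n = len(seq)
        codes = encode_protein(seq)
        has_amb = bool((codes == 255).any())
        if has_amb and config.skip_ambiguous:
            # cumulative ambiguous-residue count -> O(1) per-window test
            bad = np.concatenate(([0], np.cumsum(codes == 255)))
        for k in config.lengths:
            if n < k:
                continue
            if has_amb and config.skip_ambiguous:
                starts = np.nonzero(bad[k:] - bad[:-k] == 0)[0]
            else:
                starts = range(n - k + 1)
            window_counts[k] += len(starts)
            for i in starts:
                pep = seq[i : i + k]
                if track_all_sources:
                    prev = sources.get(pep)
                    if prev is None:
                        sources[pep] = (prot.id,)
                    elif prot.id not in prev:
                        sources[pep] = prev + (prot.id,)
                else:
                    sources.setdefault(pep, prot.id)
    return DigestResult(sources=sources, window_counts=window_counts)
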