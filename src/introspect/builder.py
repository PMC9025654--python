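"""Targeted-database construction: the core two-round search support.

Pipeline (given first-round peptide identifications and a proteome):

1. restrict first-round hits to the configured lengths (9-11 by default);
2. Gibbs-cluster them into motif groups over the 9-mer core;
3. train a PSSM per (cluster, length) with enough training peptides;
   lengths short of ``min_train`` in a cluster fall back to the cluster's
   aligned 9-mer core matrix;
4. enumerate the full unspecific k-mer space of the proteome;
5. keep k-mers whose best motif score strictly exceeds the threshold;
6. add *every* first-round peptide regardless of motif score or proteome
   membership — the second-round search then covers everything the first
   round found, so a single global FDR applies to the combined result;
7. optionally add contaminant-derived k-mers (tagged, unfiltered) so
   contaminant assignments can still be eliminated after the search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .digestion import DigestConfig, DigestResult, enumerate_kmers
from .errors import DataError
from .gibbs import GibbsConfig, cluster_peptides, retained_peptides
from .io_formats import PeptideHit, ProteinRecord
from .pssm import (
    Pssm,
    background_frequencies,
    filter_kmers,
    model_name,
    score_peptide,
    score_with_deletions,
    train_pssm,
)

logger = logging.getLogger(__name__)

PROV_MOTIF = "motif"
PROV_FIRST_ROUND = "first_round"
PROV_CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class BuildConfig:
    digest: DigestConfig = DigestConfig()
    gibbs: GibbsConfig = GibbsConfig()
    omega: float = 0.1
    threshold: float = 0.3
    min_train: int = 20
    #: warn when the first-round set is too small to train reliable motifs
    min_total_hits: int = 500
    include_contaminant_kmers: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise DataError("threshold must be finite")
        if self.min_train < 1:
            raise DataError("min_train must be >= 1")


@dataclass
class PeptideEntry:
    provenance: set[str]
    best_score: float | None = None
    best_model: str | None = None
    via_core: bool = False


@dataclass
class TargetedDatabase:
    """Deduplicated targeted peptide set with per-peptide provenance."""

    peptides: dict[str, PeptideEntry]
    summary: dict[str, object]
    pssms: list[Pssm] = field(default_factory=list)
    core_pssms: list[Pssm] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peptides)

    def provenance_counts(self) -> dict[str, int]:
        counts = {PROV_MOTIF: 0, PROV_FIRST_ROUND: 0, PROV_CONTAMINANT: 0}
        for entry in self.peptides.values():
            for tag in entry.provenance:
                counts[tag] += 1
        return counts


def build_targeted_database(
    first_round: Sequence[PeptideHit],
    proteome: Sequence[ProteinRecord],
    contaminants: Sequence[ProteinRecord] = (),
    config: BuildConfig = BuildConfig(),
) -> TargetedDatabase:
    """Run the motif-guided pipeline and compose the targeted database."""
    if not proteome:
        raise DataError("build: empty proteome")
    lengths = set(config.digest.lengths)
    hits = [h for h in first_round if h.length in lengths]
    n_excluded = len(first_round) - len(hits)
    if n_excluded:
        logger.info("%d first-round hit(s) outside configured lengths excluded", n_excluded)
    if not hits:
        raise DataError("build: no first-round peptides within configured lengths")
    if len(hits) < config.min_total_hits:
        logger.warning(
            "only %d first-round peptides (<%d): motif models may be weak",
            len(hits),
            config.min_total_hits,
        )

    background = background_frequencies(list(proteome))
    gibbs_cfg = replace(config.gibbs, rng_seed=config.rng_seed)
    sequences = sorted({h.sequence for h in hits})
    result = cluster_peptides(sequences, gibbs_cfg, background=background)
    retained = retained_peptides(result)
    logger.info(
        "clustering: selected K=%d, trash=%d of %d peptides",
        result.selected_K,
        retained.n_trash,
        len(sequences),
    )

    pssms: list[Pssm] = []
    core_pssms: list[Pssm] = []
    for cluster_idx, members in retained.groups.items():
        if not members:
            continue
        cid = cluster_idx + 1
        by_length: dict[int, list[str]] = {}
        for pep, _aln in members:
            by_length.setdefault(len(pep), []).append(pep)
        for length, peps in sorted(by_length.items()):
            if len(peps) >= config.min_train:
                pssms.append(
                    train_pssm(peps, background, config.omega, cluster_id=cid)
                )
        # aligned 9-mer cores: fallback model for under-trained lengths
        cores = ["".join(pep[k] for k in aln.core_indices(len(pep))) for pep, aln in members]
        core_pssms.append(
            train_pssm(cores, background, config.omega, cluster_id=cid)
        )
    if not pssms and not core_pssms:
        raise DataError("build: no cluster produced a trainable model")
    logger.info(
        "trained %d length-specific PSSM(s) and %d core model(s)",
        len(pssms),
        len(core_pssms),
    )

    digest = enumerate_kmers(list(proteome), config.digest)
    full_space = len(digest)
    logger.info(
        "unspecific space: %d unique k-mers (%s windows per length)",
        full_space,
        digest.window_counts,
    )

    passing = filter_kmers(
        digest.by_length(),
        pssms,
        threshold=config.threshold,
        core_fallback=core_pssms,
        max_deletions=config.gibbs.max_deletions,
        fallback_lengths={h.length for h in hits},
    )
    logger.info(
        "motif filter (> %g): %d of %d k-mers pass (%.3f%%)",
        config.threshold,
        len(passing),
        full_space,
        100.0 * len(passing) / full_space if full_space else float("nan"),
    )

    peptides: dict[str, PeptideEntry] = {
        pep: PeptideEntry(
            provenance={PROV_MOTIF},
            best_score=rec.best_score,
            best_model=rec.best_model,
            via_core=rec.via_core,
        )
        for pep, rec in passing.items()
    }
    for hit in hits:
        entry = peptides.get(hit.sequence)
        if entry is None:
            entry = PeptideEntry(provenance={PROV_FIRST_ROUND})
            entry.best_score, entry.best_model, entry.via_core = _best_score(
                hit.sequence, pssms, core_pssms, config.gibbs.max_deletions
            )
            peptides[hit.sequence] = entry
        else:
            entry.provenance.add(PROV_FIRST_ROUND)

    contaminant_space = 0
    if contaminants and config.include_contaminant_kmers:
        cont_digest = enumerate_kmers(list(contaminants), config.digest)
        contaminant_space = len(cont_digest)
        for pep in cont_digest.sources:
            entry = peptides.get(pep)
            if entry is None:
                peptides[pep] = PeptideEntry(provenance={PROV_CONTAMINANT})
            else:
                entry.provenance.add(PROV_CONTAMINANT)

    per_length: dict[int, int] = {k: 0 for k in config.digest.lengths}
    for pep in peptides:
        per_length[len(pep)] += 1
    summary: dict[str, object] = {
        "n_peptides": len(peptides),
        "n_first_round": len(hits),
        "selected_K": result.selected_K,
        "n_trash": retained.n_trash,
        "cluster_sizes": result.selected.cluster_sizes,
        "full_space_size": full_space,
        "full_space_per_length": dict(digest.window_counts),
        "contaminant_space_size": contaminant_space,
        "per_length_counts": per_length,
        "reduction_ratio": len(peptides) / full_space if full_space else float("nan"),
        "threshold": config.threshold,
        "rng_seed": config.rng_seed,
    }
    return TargetedDatabase(
        peptides=peptides, summary=summary, pssms=pssms, core_pssms=core_pssms
    )


def _best_score(
    peptide: str,
    pssms: Sequence[Pssm],
    core_pssms: Sequence[Pssm],
    max_deletions: int,
) -> tuple[float | None, str | None, bool]:
    """Best available motif score for an injected first-round peptide."""
    exact = [(score_peptide(p, peptide), model_name(p)) for p in pssms if p.length == len(peptide)]
    if exact:
        s, name = max(exact)
        return s, name, False
    cores = [
        (score_with_deletions(c, peptide, max_deletions), model_name(c, core=True))
        for c in core_pssms
        if 0 <= len(peptide) - c.length <= max_deletions
    ]
    if cores:
        s, name = max(cores)
        return s, name, True
    return None, None, False


def build_report(db: TargetedDatabase) -> tuple[str, dict[str, object]]:
    """Human-readable and flat machine-readable build summary."""
    s = db.summary
    prov = db.provenance_counts()
    table: dict[str, object] = {
        "n_peptides": s["n_peptides"],
        "n_first_round": s["n_first_round"],
        "selected_K": s["selected_K"],
        "n_trash": s["n_trash"],
        "full_space_size": s["full_space_size"],
        "contaminant_space_size": s["contaminant_space_size"],
        "reduction_ratio": s["reduction_ratio"],
        "threshold": s["threshold"],
        "rng_seed": s["rng_seed"],
        "provenance_motif": prov[PROV_MOTIF],
        "provenance_first_round": prov[PROV_FIRST_ROUND],
        "provenance_contaminant": prov[PROV_CONTAMINANT],
    }
    for k, v in sorted(s["per_length_counts"].items()):  # type: ignore[union-attr]
        table[f"n_peptides_len{k}"] = v
    for k, v in sorted(s["full_space_per_length"].items()):  # type: ignore[union-attr]
        table[f"full_space_windows_len{k}"] = v
    for i, size in enumerate(s["cluster_sizes"], start=1):  # type: ignore[arg-type]
        table[f"cluster{i}_train_size"] = size
    lines = ["targeted database summary", "-" * 25]
    lines += [f"{k}\t{v}" for k, v in table.items()]
    return "\n".join(lines), table
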