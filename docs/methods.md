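# Methods

This note documents the models and procedures implemented in
`introspect`, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic benchmark does and does
not establish.

## Search-space model

HLA class I ligands are 9–11 residues long and arise from unspecific
proteasomal cleavage, so the candidate space for a no-enzyme search is
every k-mer window of the proteome for k ∈ {9, 10, 11}. `digestion`
enumerates these windows streaming, deduplicates across proteins and
lengths, and keeps one representative source protein per peptide by
default (full provenance is available but costs memory; the database
builder only needs existence). Windows containing ambiguity codes
(B, J, O, U, X, Z) are skipped by default since a 20-residue scoring
matrix cannot score them; isoleucine and leucine are kept distinct.
Pre-deduplication window counts per length are reported and satisfy the
exact identity `count(k) = Σ_proteins max(0, n − k + 1) − skipped`.

## Motif model (PSSM)

A cluster of ligands of one length L is modelled position-independently.
With training frequencies `F[i,a]`, background frequencies `B[a]`
(computed from the supplied proteome FASTA, ambiguity codes excluded,
floored at 1e-6 and renormalised), and pseudocount weight ω:

    f~[i,a] = (F[i,a] + ω·B[a]) / (1 + ω)
    P[i,a]  = log2(f~[i,a] / B[a])            (scoring_form = log_odds)

The motif score of a peptide is the plain sum `Σ_i P[i, a_i]` with no
length normalisation. Under this form a peptide drawn residue-wise from
the background has expected score ≈ 0 wherever the model matches the
background and pays an explicit penalty at anchor positions it misses,
which is consistent with a small positive filter threshold. A literal
alternative form, `P[i,a] = log2(F[i,a] + ω·B[a])` (`as_printed`), is
retained as an option; being a sum of log-frequencies it is negative for
every peptide and cannot sit on the same side of a positive threshold,
which is why it is not the default.

**Parameters.** ω defaults to 0.1 (dimensionless weight of the background
pseudocount mass relative to the observed frequency mass; larger ω
shrinks every log-odds entry monotonically toward 0). The filter
threshold defaults to 0.3 bits and is applied strictly (`score > 0.3`).
Models are trained per (cluster, length) when at least `min_train = 20`
peptides of that length are in the cluster.

**Fallback for under-trained lengths.** A length with too few training
peptides in a cluster is scored through the cluster's aligned 9-mer core
matrix, maximising over the legal internal-deletion placements, and
flagged `via_core`. The builder restricts this fallback to lengths that
actually occur among the first-round hits: scoring a length with *zero*
identified ligands as the best of up to 36 alignments admits an order of
magnitude more background k-mers than a directly trained matrix would,
and a length with no first-round evidence has no support in the sample.
Lengths outside both categories are dropped with a warning.

## Gibbs clustering

First-round peptides (all lengths jointly) are partitioned into K motif
clusters over a 9-mer core for each K in 1..6. A peptide of length L
aligns to the core by deleting L − 9 internal positions; the first and
last residues are never deleted, preserving the P2-proximal and
C-terminal anchor geometry. Insertions are not supported.

The sampler state is a (cluster, alignment) pair per peptide. One sweep
visits every peptide in seeded-random order, removes it from its
cluster's counts, scores every (cluster, alignment) candidate by the
peptide's summed log₂-odds under the leave-one-out pseudocount-smoothed
cluster frequencies, and samples a candidate with probability
∝ exp(score / T). Ten sweeps are run at each temperature of a geometric
schedule from 1.5 to 0.05 over 20 steps, followed by a greedy (argmax)
polish iterated to a fixed point; argmax ties break toward the lowest
candidate index, so runs are fully deterministic given the seed. Five
seeded restarts are run per K and the best objective kept.

**Two pseudocount weights.** The sampler smooths with ω = 1.0 while the
final scoring matrices and the trash rule use ω = 0.1. With light
smoothing the per-position log-odds noise of a ~100-peptide cluster is
comparable to a two-anchor motif signal and the chain freezes in mixed
configurations in which each cluster has memorised its members'
non-anchor residues; heavier smoothing compresses that noise while the
anchor signal stays dominant. This is a search device only — it does not
change the reported models.

**Trash cluster.** After the polish, any peptide whose best summed
log₂-odds fit to its own cluster (at ω = 0.1) is below the threshold 2 is
moved to the trash and excluded from the frequency matrices. The
threshold is interpreted on the total-score scale (bits summed over the
9 core positions); a per-position interpretation is available
(`trash_score_scale="per_position"`) but at 2 bits/position it discards
even peptides drawn exactly from a strong two-anchor motif, so the total
scale is the default. Trash peptides do not train models but, having
passed the first-round FDR, are still injected into the targeted
database.

**Model selection.** The objective of a K-cluster solution is

    KLD = Σ_c (n_c / N) · a_c · Σ_{p,a} f~_cpa · log2(f~_cpa / B_a)
          − λ · Σ_{c<c'} max(0, ρ(F_c, F_c'))

with `a_c = min(1, n_c / (σ·9))` attenuating clusters smaller than σ·9
peptides (σ = 5), λ = 0.8, and ρ the Pearson correlation between
vectorised cluster frequency matrices, clipped at zero so only positive
motif similarity is penalised. Two choices matter here. First, the KLD
term uses the *smoothed* frequencies: the raw plug-in KLD estimate
carries an upward small-sample bias of roughly (19·9)/(2·ln2·n_c) bits,
which systematically rewards splitting a clean cluster in two; smoothing
removes that reward. Second, clusters are weighted by their fraction
n_c/N rather than their absolute size, which keeps the λ penalty on a
commensurate scale. The selected K maximises the objective; ties break
toward smaller K (a run that leaves clusters empty scores exactly like
the smaller effective K).

## Targeted database composition

The builder restricts first-round hits to the configured lengths (warning
when fewer than 500 remain, since length-specific models then become
unreliable), clusters them, trains the per-(cluster, length) PSSMs and the
per-cluster core matrices, enumerates the proteome k-mer space, filters at
the threshold, and injects every first-round peptide — including peptides
that fail the motif filter or are absent from the proteome (e.g. a
neoepitope searched from a custom FASTA). Contaminant proteins cannot
ride along as whole sequences in a peptide-per-entry no-cleavage FASTA,
so their 9–11-mers can optionally be added unfiltered with a
`contaminant` provenance tag (off by default), keeping post-search
contaminant elimination possible. The output FASTA is written in
lexicographic peptide order with provenance and best score in the header;
identical inputs produce byte-identical files.

## Evaluation: PCC_aaf

For two equal-length peptide sets, each position yields two empirical
pmfs over the 20 residues; their Pearson correlation is computed over the
20 residue categories (population divisor — PCC is scale-free so the
convention cancels) and averaged over the requested (1-based) positions.
A position where either pmf is numerically uniform (σ ≤ 1e-12) has an
undefined correlation; it is reported as missing and excluded from the
mean rather than imputed. Sets of different lengths are not aligned;
each call requires a uniform length.

## Synthetic benchmark

`synthetic` provides the ground-truth generators used by the tests and
the examples:

* **Motif peptide sets** — positions draw from a background distribution
  except at anchors, where the anchor residue receives a fixed mass
  (default 0.7) and the remainder is spread over the other residues in
  proportion to background. This emulates the one-dominant-residue
  anchor structure of HLA class I logos but *not* real motifs'
  multi-residue anchor preferences or correlated secondary positions.
  At mass 0.7, about 9% of motif peptides carry no anchor residue at all
  and ~3% carry another motif's anchor by chance; such peptides are
  information-theoretically unassignable, which bounds any clustering
  agreement measured against generating labels (assigning peptides with
  the true generating models and the same trash rule yields a mean
  retained-peptide adjusted Rand index of ≈ 0.89 under the default
  two-motif benchmark conditions — no implementation can beat that
  ceiling on average).
* **Planted proteomes** — each planted peptide is embedded verbatim in a
  background-sampled host protein, so unspecific enumeration provably
  recovers it.
* **Two-round simulation** — deliberately minimal: a spectrum's true
  match scores Normal(μ_t, σ); its best random match is the maximum of
  `ceil(c·|db|)` Normal(μ_r, σ) draws (c = 1e-3), and decoys are a
  same-size reversed-sequence database scored the same way.
  Identifications are counted at the most permissive score cutoff whose
  decoy/target ratio stays at or below the FDR level. The model contains
  no spectra, fragment matching or rescoring; it demonstrates only the
  competition mechanism — the maximum of more random draws is larger, so
  bigger databases raise decoy scores and lose true identifications at a
  fixed FDR. Magnitudes are not calibrated to any instrument or engine.

Because the generator draws positions independently, uses single-residue
anchors and a clean background, passing tests establish the pipeline's
correctness and its qualitative behaviour (space reduction, superset
rule, sensitivity direction), not quantitative performance on real
immunopeptidome data.

## Problem sizes and defaults used in the checks

The test suite and `scripts/acceptance.py` run scaled-down study
conditions chosen to exercise every code path quickly: clustering checks
use 100 + 100 peptides, cluster range 1–3 and 2–3 seeded restarts;
builds use planted proteomes of 500 × 200–400-residue filler proteins
(~6 × 10⁵ unique 9–11-mers); the simulation uses 2000 spectra against
nominal database sizes 10⁴–10⁶. The full defaults (cluster range 1–6,
5 seeds) remain the recommended settings for real data.

## Known limitations

* The PSSM is position-independent and length/cluster-specific; small
  first-round sets (< 500 peptides) train weak models, and no transfer
  from external binding data is attempted.
* The Gibbs sampler's internal constants (temperature schedule, sampler
  ω) are fixed heuristics validated on synthetic mixtures, not fitted to
  data.
* `pcc_aaf` compares same-length sets only.
* The search simulation is a mechanism demonstration, not a predictor of
  identification counts.
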