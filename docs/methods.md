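# Methods

## Composite model

Each de novo candidate of a spectrum is scored with the positive affine
combination

    composite = (1 − α − β)·A + α·(100 − M) + β·R ,   α, β ≥ 0,  α + β ≤ 1.

`A` is the engine's average local confidence on [0, 100]. `M` is the MHC
eluted-ligand percentile rank on [0, 100] (smaller = stronger predicted
presentation), reduced over the sample's 1–6 class I alleles by the
**minimum** — the best-binding-allele convention of the upstream
predictors; the reduction is a package choice, as multi-allele samples
admit no unique answer. `R` is the retention-time agreement
`100·(ΔT_max − ΔT)/(ΔT_max − ΔT_min)` with `ΔT = |T_pred − T_obs|` in
minutes. Because the combination is affine with non-negative weights and
every component lies in [0, 100], the composite lies in [0, 100]; at
`α = β = 0` it equals `A` exactly, so the baseline is always contained in
the model family (and in the weight grid).

Candidate gating precedes scoring: ALC ∈ [50, 100] and M ≤ 10 (the M gate
removes predicted non-binders, typically co-purification background). Both
gates are applied per candidate. A spectrum whose candidates all fail a
gate is reported unassigned with the failing gate as the reason — there is
deliberately no fall-back to the ALC-only answer, since an all-non-binder
candidate list is itself evidence against the spectrum being an MHC ligand.

Ties in the final ranking break deterministically: higher `A`, then
lexicographically smaller peptide. All sequence comparisons happen after
collapsing isoleucine to leucine on both sides (I/L are isobaric and
indistinguishable by standard fragmentation).

## R normalisation scope

`ΔT_min`/`ΔT_max` are taken over all gated candidates of the run being
scored, not per spectrum: a per-spectrum scope would re-scale R against
whatever decoys happen to populate each list and make R values
incomparable across spectra. At apply time, ΔT values outside the stored
bounds clamp to the boundary scores (100/0); a degenerate run
(`ΔT_max = ΔT_min`) scores 100 everywhere, making R a no-op rather than an
error.

## RT calibration

Raw predictor output is mapped to observed minutes by an affine
least-squares fit on anchor pairs — the top candidate of every spectrum
with ALC ≥ 95, a small but reliable identification set. The fit reports
slope, intercept, anchor count and residual SD; fewer than two anchors or
zero predictor variance is an error (with the advice to lower the anchor
threshold). An optional Theil–Sen (median-slope) mode tolerates the
occasional wrong anchor. This affine recalibration deliberately replaces
per-dataset fine-tuning of a deep RT network: the contract — adapt a black
box predictor to a chromatographic setup using high-confidence anchors —
is preserved without GPU training, at the cost of not correcting
sequence-dependent prediction error.

## Evaluation statistics

* **F-rank**: rank of the true peptide in the descending-score candidate
  list divided by the list length; tied scores contribute their average
  competition rank. Bounds: 1/n ≤ F-rank ≤ 1, with 1/n iff the truth is
  the unique top. Tie handling is property-tested against a brute-force
  mean over all orderings of the tie group.
* **FSR** (full-sequence recall): fraction of spectra whose top candidate
  equals the truth up to I/L. The denominator is the *recoverable* spectra
  (truth present in the candidate list); an all-spectra FSR is a secondary
  statistic obtainable by scaling with the recoverable fraction.
* **FDP** = 1 − TP/(TP+FP) cumulatively over a score-sorted validation
  series. The bundled 19-row lncRNA validation series yields a final FDP of
  8/19 = 42.1% and 1/7 = 14.3% in the score ≥ 95 region. Note the series'
  originally printed per-row FDP values are not exactly cumulative
  FP/(TP+FP) at every row (e.g. 0.13 printed where 1/7 = 0.143); this
  package computes the formula as defined and does not reverse-engineer
  the original rounding.
* Confidence regions on the composite score: region 1 ≥ 95,
  region 2 [90, 95), region 3 [80, 90), below otherwise.

## Cross-validation and weight selection

Training ground truth is built from database-search hits with
−10lgP ≥ 20 (≈ <1% PSM-level FDR), peptide length 8–13 and allele-reduced
M ≤ 10; the recoverable flag is exactly the candidate-membership test
after I/L collapse. For discovery mode, the complementary filter removes
every spectrum with a DB hit above the −10lgP threshold.

Folds are 8-mer disjoint: peptides sharing any 8-mer substring are unioned
into connected components (union-find over a k-mer → first-owner map), and
components are assigned whole to folds, heaviest first into the currently
lightest fold, weighted by spectrum count ("equal parts" balances spectra;
balancing unique peptides is the other defensible reading). Disjointness is
an exact invariant, checked exhaustively in the tests; fold-size imbalance
is bounded by the largest component's weight. The seed only permutes
equal-weight components.

Weights are selected by exhaustive evaluation of the simplex grid
(default step 0.01; a 1-D mode fixes β = 0 for the two-factor model),
minimising the mean F-rank of the training spectra; ties break toward
smaller α then smaller β, so the simplest model wins. Per CV fold, weights
are fitted on the other k−1 folds and applied to the held-out fold only;
held-out predictions are concatenated for the overall FSR / mean F-rank.
Wilcoxon signed-rank (per-spectrum F-ranks) and paired t (per-fold FSR)
wrappers are provided for reporting; they are scipy calls, not part of the
method.

## Origin mapping

Strict stepwise precedence per peptide: exact canonical-protein substring
hit → `HumanProtein`; else any equal-length protein window at Hamming
distance exactly 1 (substitutions only, no indels) → `OneAASubstitution`;
else exact hit in the translated non-canonical space → `NonCanonical`,
carrying the multi-label biotype set of *all* such hits (no hierarchy
among biotypes — a peptide with several possible origins cannot be
faithfully assigned to one); else `Unmatched`. Hamming-1 search against
the non-canonical space is deliberately not attempted: distance-1 matches
are only interpreted as germline/somatic substitutions of annotated
proteins.

The Hamming-1 search is pigeonhole seed-and-verify: any window within
distance 1 must contain one half of the peptide exactly, so both halves
are located by exact substring search and the full window verified. It is
property-tested for exact equality against a position-by-position
brute-force scan. I/L equivalence is obtained by collapsing both the query
and the reference text, so I↔L differences count as distance 0.

Nucleotide references are conceptually translated — six frames for genomic
sequences, three for transcripts (`src=transcriptome` header tag) — with
fragments split at stop codons and at codons containing N ('X'), and
fragments shorter than 8 aa discarded (nothing below the peptide length
floor can match). Offsets are 0-based half-open internally; reports print
1-based inclusive coordinates. Biotype labels ride on a `biotype=` FASTA
header key, so additional resources (lncRNA databases, transposable-element
sets) are plain extra FASTA files with tags, not bespoke parsers. Indexing
is streaming over fragments; tests and fixtures use kilobase-scale
references and no whole-genome performance is claimed.

Engine modification tags in candidate strings (e.g. oxidised methionine
mass tags) are stripped by default before scoring and mapping — composite
scoring operates on plain sequence; a reject mode exists for pipelines that
want to fail loudly instead. How modified candidates should best be passed
to binding predictors is genuinely ambiguous; stripping is the documented
choice.

## Synthetic data generator

The generator emulates the candidate-list level at which the re-scorer
operates; it simulates no fragment spectra. Per spectrum:

* the true 8–13-mer is drawn from an allele anchor motif (anchor positions
  2 and C-terminus; modal anchor residue probability 0.9 by default, other
  positions uniform), lengths from a distribution peaked at 9-mers;
* decoys come from the schemes that produce real de novo ambiguity:
  N-terminal transposition (always included when applicable), internal
  permutation, mass-compensated isobaric substitution (GG↔N, GA↔Q, applied
  only in compensated pairs so length is preserved), and point errors;
* ALC: the truth beats the best decoy by |N(0, 1.5)| with probability
  `p_top` (default 0.70 — the ALC-only baseline FSR), otherwise trails it
  by 0.2 + Exp(mean 2.5). The near-miss structure matters: ambiguous
  permutations score close to the truth, which is precisely why an
  intermediate α is optimal rather than α → 1;
* M-ranks: by default, percentile ranks of every candidate against the
  motif PSSM over a uniform background (truth systematically lower);
  controlled-regime fixtures draw ranks from configured uniform ranges;
* observed RT = 30 + 0.8·(Kyte–Doolittle sum) + N(0, 0.5) minutes, raw
  predictions = KD sum + N(0, 0.3), so calibration must recover the affine
  map. Permutation decoys are composition-preserving and therefore
  RT-invisible — the modest marginal value of R is a structural property
  of the decoy space, not a tuning accident; point-substitution decoys are
  the ones R can catch.

Regime presets: `m_dominant` (truth's rank below every decoy's, ALC drawn
i.i.d. with the decoys — M alone is perfect, A pure noise), `a_dominant`
(`p_top = 1`, M and RT pure noise), `mixed` (all three informative,
overlapping). A recoverable fraction (default 0.923) of spectra carry the
truth in the candidate list; the rest emulate non-discoverable spectra.

What passing tests on this generator shows: the estimator machinery (gates,
normalisation, grid search, CV, statistics) is correct and recovers
injected signal regimes. What it does not show: real-data performance —
the generator has no fragment-level noise model, no allele-specific spectral
quality differences, no chimeric spectra, and its M/RT signal levels are
set, not measured.

## Numerical choices and problem sizes

Score comparisons use an absolute tolerance of 1e-9 for tie detection.
Grid step defaults to 0.01; the cross-validation calls in the acceptance
path use 0.02, which changes no regime conclusion and quarters the work.
Simulated acceptance fixtures use 2000 spectra × 20 candidates; unit-test
fixtures are smaller. Background size for the toy PSSM rank is 4000–10000
draws per length. All RNG is `numpy.random.default_rng` seeded explicitly;
outputs are ordered deterministically, so identical configurations produce
byte-identical files.

## Known limitations

* The affine RT calibration cannot correct sequence-dependent predictor
  bias; only a scale/offset per chromatographic setup.
* The M reduction (minimum over alleles) discards per-allele provenance;
  allele assignment of identifications is out of scope.
* Origin mapping is linear-match only: no spliced or junction-aware
  mapping, no proteasomal splicing, no PTM-aware matching — the `Unmatched`
  category absorbs everything those mechanisms would explain.
* FDP estimates from small validation series carry large binomial error
  (a 1/7 region estimate moves by 14 points per flipped call).
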