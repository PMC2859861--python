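# Methods

## The screening problem

Suppression subtractive hybridization (SSH) produces cDNA libraries
enriched for transcripts that differ between a *tester* and a *driver*
sample, while normalizing transcript abundance so that rare messages are
recovered.  Enrichment is imperfect, so each clone must be screened
before sequencing.  `subscreen` screens the clones on two-colour
microarrays spotted with the library itself, hybridised with combinations
of four cDNA samples: unsubtracted treated (UT), unsubtracted control
(UC), subtracted treated (ST, the forward-library material) and
subtracted control (SC, the reverse-library material).

Two log2 ratios summarise each clone:

* **ER3** = log2(UT/UC) for forward clones, log2(UC/UT) for reverse
  clones — the treatment effect on the transcript.
* **inverse ER2** = log2(UT/ST) forward, log2(UC/SC) reverse — negative
  values mean the transcript was rare before subtraction and the SSH
  step enriched it.

## Pre-processing model

Arrays constructed from an SSH library violate the standard loess
assumption that most spots are unchanged — the library was *selected*
for change.  Normalization therefore uses only the alien spike-in
control spots (globin, its, nptII, gfp), added at fixed mass ratios
(45 : 45 : 4.5 : 0.45 ng) to both labelled targets and printed as
five-step two-fold dilution series.  Their true log-ratio is zero at
every intensity.

1. **Spot weights.**  Weight 0 when the GenePix flag is negative or
   either channel's signal-to-noise ratio (foreground − background over
   background SD, or the scanner's own SNR column) is below 3; else 1.
   Weight-0 spots are excluded from both curve fitting and model
   fitting, but still get normalized values.
2. **Background correction** fits the normexp convolution
   (x = B + S, B ~ N(μ, σ²), S ~ Exp(α)) per array-channel by exact
   maximum likelihood (Nelder–Mead from a moments start) and replaces
   each net intensity with E[S | x] + offset.  The offset (default 50
   intensity units) damps log-ratio variance at low intensity.  The
   conditional mean uses log-scale normal functions so the Mills ratio
   is stable hundreds of SDs into the tail.  A degenerate fit (σ → 0 or
   α → 0) falls back to thresholded net intensities with a warning.
3. **M/A values**: M = log2(Cy5/Cy3), A = (log2 Cy5 + log2 Cy3)/2.
4. **Within-array loess**: per print-tip group, a robust local-linear
   loess of M on A (span 0.3, 4 robustifying iterations) is fitted
   through usable control spots only and subtracted from every spot's M.
   Outside the controls' A range the boundary fit is held constant —
   constant extrapolation avoids polynomial tails in regions where only
   library spots live.  Groups with fewer than 10 usable controls fall
   back to an array-wide control loess (logged).  A partial-weight
   option adds a deterministic thinning of library spots to the fit.
5. **Aquantile**: A values are quantile-normalized across arrays (each
   array's sorted A replaced by the across-array mean at that rank; ties
   get the mean of their ranks' reference values).  M is untouched.

## Linear model and moderation

Within-array duplicate spots of a clone are collapsed to their
weighted-mean M per array before fitting; averaging is unbiased and
keeps degrees-of-freedom bookkeeping per array.  For each contrast the
per-clone model is a weighted mean of sign-corrected values
y_i = orientation_i · M_i (orientation +1 when the contrast's numerator
sample was Cy5, −1 for the dye swap), giving beta, residual variance s²
on d = (#used − 1) df, and unscaled standard deviation 1/√Σw.

Variances are shrunk with the standard empirical-Bayes scheme: the
prior (d0, s0²) is estimated by method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) (trigamma inverse by Newton), and
s²_post = (d0·s0² + d·s²)/(d0 + d).  The moderated t uses d0 + d df
(normal when d0 = ∞).  Clones with a single usable array (d = 0) get
s²_post = s0² — the shrinkage is exactly what rescues them.  p-values
are BH-adjusted within each library's clone universe (configurable, to
accommodate alternative universe counts).  The B-statistic is the log
posterior odds of differential expression with prior proportion 0.5 —
appropriate for a library in which roughly half the clones are expected
to be real — and the alternative-variance hyperparameter v0 is estimated
by quantile moment-matching of the top |t| values (floored at 0.1 times
the mean unscaled variance so B stays finite on null data; v0 moves B
but never the t ranking).  All of this is cross-checked against the
reference R implementation in the test suite and agrees to ~1e-6.

## Top tables, quadrants, plots

The primary table per library carries the published eight columns
(ID, logFC(ER3), AveExpr, t, P.Value, adj.P.Val, B, invER2) sorted by p
(ties: |t| descending, then ID), plus quadrant and library columns.  A
secondary table reports the ER2 contrast's own statistics.  Quadrant
labels follow the published convention — forward library: (+,−)
Up.Rare, (+,+) Up.Abundant, (−,+) Down.Rare, (−,−) Down.Abundant; the
reverse library flips the Up/Down half — with zeros joining the
positive side for determinism.  The ER plot highlights the
min(300, #{adj p < 0.05}) most significant clones and reports quadrant
counts and the significant / positive-B percentages for both the full
and the highlighted populations.

## Sequence redundancy

Sequenced clones are trimmed by exact affine-gap local alignment
(match +1, mismatch −2, gap open −5, extend −2) against a bundled
vector/adaptor database; maximal terminal runs of hits (score ≥ 16) are
removed iteratively from both ends and strands, an internal hit rejects
the read as chimeric, and inserts shorter than 30 nt are rejected
(shorter fragments cannot reach the E-value cutoff anyway).  The
bundled database combines the public nested-PCR SSH adaptor sequences
with *synthetic* stand-in vector arms (generated, clearly labelled in
the FASTA; swap in a real UniVec subset for production use).

Pairs of trimmed clones are compared by local alignment over both
strands with an 11-mer shared-word pre-filter; the Karlin–Altschul
E-value E = K·m·n·e^(−λS) uses λ = 1.28, K = 0.46, which approximate
ungapped nucleotide-BLAST statistics for this scoring and are
configurable.  Redundant partner groups are the connected components of
E < 1e-10 (single-linkage closure — the only partition stable under
incremental uploads); the representative is the longest trimmed member
(ties: smallest id), and group ids are ordered by smallest member id so
grouping is input-order invariant.  Exports join groups to top tables,
imported annotation files (best hit with E < 1e-10 becomes the priority
annotation, manually overridable) and GAL files.

## Synthetic experiments

The generator emulates the screening design end to end: 2000+2000
clones printed in duplicate on mirrored half-slides of a 16 × 24 × 22
grid, control dilution series in row 12 of the first four blocks of
each half (176 control spots/array), three contrasts × 4 arrays with
two dye swaps each.  Intensities follow the normexp assumption exactly:
an exponential spot-deposition amount *shared between channels* (spot
morphology cancels in the ratio, as on real arrays), scaled by
2^(sample log2 level), plus normal background; a misspecified
gamma-deposition mode exists for robustness checks.  Dye bias is a
smooth cubic in A applied to the Cy5 channel.  Defaults: 10% truly DE
clones at |log2 ratio| ~ N(2, 0.5) (8% assigned to the wrong library,
matching the reported subtraction quality), 88% rare clones, per-array
clone noise 0.35 log2 units, per-spot channel noise 0.07, ~3% bad
spots.  Noise scales were set so the pre-normalization control-spot M
SD is ≈ 0.18, the value reported for the real screen; after
normalization the synthetic SD settles ≈ 0.13 rather than the reported
0.10 because the dimmest dilution spots carry background-driven ratio
noise that no intensity-dependent correction can remove.

What passing on synthetic data does *not* show: real arrays have
spatial artefacts beyond print-tip structure, saturation, carry-over
between adjacent spots and genuinely non-normexp intensity
distributions; the generator models none of these, so the suite
validates the statistical machinery, not scanner physics.

A clone FASTA with planted redundancy (overlapping fragments of shared
transcripts, some reverse-complemented, flanked by adaptor/vector
sequence) and a truth table accompany each bundle; duplicates and
redundant partners share their transcript's true values.

## Numerical choices and degenerate inputs

* Zeros in quadrant classification join the positive side; NaN gives
  "Unclassified".
* Aquantile ties get the mean of their ranks' reference values
  (permutation invariance).
* In the noiseless regime the generator fixes spot deposition at 1 and
  the variance-prior estimator pins (d0 = ∞, s0² = mean s²) when
  residual variances vanish, so exact-recovery contracts hold to float
  precision.
* The moderated-t d0 → 0 / d0 → ∞ limits reproduce the ordinary t and
  the normal-theory z to 1e-6 relative error.
* Problem sizes in the test suite: the default 2000+2000-clone bundle
  for end-to-end power (≥ 90% at adj p < 0.05, sign accuracy ≥ 99%),
  G = 20000 for variance-prior recovery, G = 5000 for null calibration,
  a 300+300-clone bundle for the remaining pipeline checks.

## Known limitations

* The loess uses `statsmodels` lowess, which has no observation
  weights; the partial-weight option is approximated by thinning.
* BLAST statistics are the ungapped Karlin–Altschul approximation;
  E-values near the cutoff can differ from NCBI BLASTN's gapped
  corrections (grouping at E < 1e-10 is far from that regime for real
  redundant clones, which share hundreds of identical bases).
* Reanalysis of the deposited cowpea array set requires the GPR files
  locally (see README); the offline test suite exercises the same code
  paths on generated data.
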