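# subscreen

Quantitative screening of suppression-subtractive-hybridization (SSH)
cDNA libraries on two-colour microarrays, plus redundancy-aware
management of the sequenced clones.

## Who this is for

SSH builds cDNA libraries enriched for transcripts that differ between a
treated ("tester") and a control ("driver") sample, normalizing
abundance so rare messages survive.  Before sinking sequencing effort
into thousands of anonymous clones, the library is screened on arrays
spotted with the clones themselves.  `subscreen` takes the raw GenePix
quantification files (GPR) of such a screen through normalization and
statistics to ranked top tables, and then groups the sequenced clones
into redundant-partner sets so each unique gene fragment is sequenced
and annotated once.

## The statistics at the core

For each clone the pipeline estimates two log2 enrichment ratios from
dye-swapped replicate arrays:

* **ER3** = log2(UT/UC) (forward library; log2(UC/UT) for the reverse
  library): differential expression under treatment,
* **inverse ER2** = log2(UT/ST) (forward; log2(UC/SC) reverse):
  negative values mean the transcript was rare and the subtraction
  enriched it,

where UT/UC/ST/SC are the unsubtracted/subtracted, treated/control cDNA
samples.  Because an SSH array's spots are *selected* for change, loess
normalization is anchored on alien spike-in control spots (globin, its,
nptII, gfp dilution series at fixed mass ratios) rather than on the
library spots.  Pre-processing is normexp background correction
(offset 50), control-spot print-tip loess of M on A, and Aquantile
between-array normalization.  Per-clone dye-swap linear models are
moderated with empirical-Bayes variance shrinkage:

    s²_post = (d0·s0² + d·s²) / (d0 + d),   t = β / (su·√s²_post) ~ t(d0+d)

with BH-adjusted p-values per library and a B-statistic (log posterior
odds of differential expression, 50% prior).  Sequenced clones are
trimmed of vector/adaptor by local alignment and grouped at a
Karlin–Altschul E-value cutoff of 1e-10 (E = K·m·n·e^(−λS)); the longest
member represents each group.

## Worked example

Simulate a small screen with known truth, then screen it:

```sh
subscreen simulate --out demo/bundle --seed 7 --n-forward 300 --n-reverse 300
subscreen screen demo/bundle --out demo/run
subscreen toptable demo/run/toptable_forward.tsv -n 5
```

The run log reports the estimated empirical-Bayes hyperparameters and
per-library summaries:

```
er3 prior: d0=10.11 s0_2=0.13282 v0=1.6347 prior_p=0.5
forward library: 9.0% significant (adj p < 0.05), 18.3% positive B,
  quadrants {'Up.Rare': 146, 'Down.Abundant': 121, 'Up.Abundant': 23, 'Down.Rare': 9}
```

and the top table carries the eight published columns plus quadrant:

```
     ID  logFC(ER3)  AveExpr       t      P.Value    adj.P.Val       B    invER2    quadrant library
c0173-F     2.22453 12.14820 16.7357 3.140140e-10 9.389020e-08 14.0872 -2.207310     Up.Rare forward
c0097-F     2.18799 10.03890 15.1311 1.107740e-09 1.656070e-07 12.5973  0.808735 Up.Abundant forward
c0203-F     1.71430  9.29915 12.9522 7.545300e-09 7.520140e-07 12.2652 -1.490440     Up.Rare forward
```

Reading the first row: clone c0173-F is 2^2.22 ≈ 4.7-fold up-regulated
by the treatment (adjusted p ≈ 9e-8; B = 14 means overwhelming odds of
real differential expression), and its negative inverse ER2 (−2.2) says
the transcript was rare before subtraction — quadrant Up.Rare, exactly
the kind of clone SSH exists to find.  With 10% of clones simulated as
truly changed, the 9.0% called significant matches the planted truth.

`subscreen group` / `subscreen export` trim and group the sequenced
clones and export annotated summaries, FASTA and GAL files; `subscreen
plot` draws the ER3 vs inverse-ER2 plot with the top-300 significant
clones highlighted.

The same operations are importable as a library
(`subscreen.pipeline.screen`, `subscreen.linmod.ebayes`,
`subscreen.seqgroup.group_redundant`, ...).

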