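# Methods

`segtail` implements the computational workflow around template-encoded
segmented poly(A) tails: describing the tail architectures, quantifying how
often plasmid amplification corrupts them, and estimating per-variant mRNA
half-lives and translation rates from reporter time courses. This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## Tail design grammar

A tail design is an ordered list of segments, each either an adenine tract
(all-A, positive length) or a heteronucleotide spacer (at least one non-A
base). Three notations are parsed interchangeably, case-insensitively, and
with U/T treated as synonyms:

* compact, `A30(CA15)11` — an `A<n>` head, then groups `(<spacer>A<n>)<k>`
  expanded left to right;
* explicit, `A30-GCATATGACT-A70` — dash-delimited alternation of tracts and
  literal spacers;
* raw sequence — segmented into maximal A-runs and non-A runs.

Designs are canonicalized at parse time: adjacent segments of the same kind
are merged, so a group with a zero-length tract concatenates its spacers.
Per-segment coordinates are 0-based, half-open on the rendered sense strand.
Rendering emits DNA (T) or RNA (U); the antisense strand is the reverse
complement of sense DNA and is only defined for DNA, since cloning inserts
are double-stranded DNA.

Novel segmented designs use tracts of 10–45 nt and spacers of 1–6 nt;
designs outside those ranges (the 90-nt homopolymer reference, the
vaccine-style 10-nt-spacer tail) parse normally and are only flagged
non-compliant.

Round-trip guarantee: `parse(render(design))` reproduces the segment list
exactly whenever spacers contain no adenine (single C/G spacers, the designs
of interest). For spacers with internal A's the rendered sequence is exact
but re-segmentation splits the spacer at its adenines — information that a
raw sequence cannot carry. `longest_adenine_run` is computed on the rendered
sequence, so A's at spacer edges join adjacent tracts; the statistic matters
because one poly(A)-binding protein needs roughly 27 consecutive adenines.

## Clone classification and instability rate

Sequenced colony tails are compared with the rendered reference:

* `intact` — exact equality;
* `shortened` — obtainable by deleting adenines only. Decided with a
  spacer-anchored matcher compiled to a regular expression: each tract of
  length n becomes `A{0,n}` and each spacer a fixed literal, matched in
  order. Backtracking makes this exact even for spacers that contain
  adenines. Contractions to zero are allowed (a fully deleted tract leaves
  its neighbouring spacers adjacent);
* `altered` — everything else: substitutions, spacer loss, insertions,
  elongation. Elongated tails are deviations in length, so they are never
  `intact`.

The instability rate is the percentage of non-intact clones (shortened and
altered both count as deviating) with a 95% Wilson score interval, which
behaves sensibly at 0/30 and small n. The module consumes pre-excised tail
sequences; locating the tail inside a longer Sanger read is left to the
caller, because no anchoring procedure is defined for it and any choice
would be untestable. One clean sequence per clone is assumed.

## Expression model

Reporter expression after transfection is a linear three-compartment
cascade in minutes,

    mRNA'     = -lambda_RNA * mRNA
    inactive' =  k_trans * mRNA - k_mat * inactive
    fluor'    =  k_mat * inactive - lambda_fluor * fluor

with initial state (m0, 0, 0) at t = 0, the moment of transfection
(delivery is instantaneous; there is no dilution, delivery-delay, or
immune-feedback term). Half-lives are t_0.5 = ln(2)/rate. Only the product
m0·k_trans is identifiable from fluorescence, so m0 is fixed to 1 and
k_trans carries the per-variant production rate on an arbitrary scale.

The closed form is evaluated through divided differences of exp(-x·t):
mRNA(t) = m0·e^(-lambda_RNA·t); the fluorophore equals m0·k_trans·k_mat
times the second divided difference on the three rate nodes. This form is
manifestly symmetric under rate permutations — the identifiability hazard
the fit must manage — and switches to the confluent limit formulas when two
(or three) rates agree to better than 1e-8 relative, where the generic
three-pole expression loses precision. An adaptive high-order integrator
(`simulate_numeric`, relative tolerance 1e-10) provides an independent
oracle; closed form and integration agree to ≤1e-6 relative across rates
spanning 1e-4–1e-1 /min and times up to 77 h.

## Hierarchical fitting

Both levels minimize mean absolute error (MAE), the one criterion the
procedure defines; an L2 inner objective is available as a config switch.

* Local level (per variant × replicate, given global k_mat and
  lambda_fluor): the fluorophore curve is k_trans times a unit shape that
  depends only on lambda_RNA, so k_trans is profiled out exactly — for MAE
  the optimum is the shape-weighted median of signal/shape ratios, for L2 a
  ratio of inner products. The remaining 1-D problem over log lambda_RNA is
  solved by golden-section refinement from multiple bracketed starts
  (half-lives 100/400/1600 min, bracket ×/÷4, clipped to bounds); the best
  refinement wins, so adding starts can only improve the objective. The
  profiled search replaces a generic 2-D start grid: it is exact in the
  scale parameter, deterministic, and an order of magnitude cheaper.
* Global level (per cell line): multi-start Nelder–Mead over
  log(k_mat, lambda_fluor) minimizing the summed local objective of all
  curves, re-solving every local problem per candidate. A 3×3 start grid
  (maturation half-lives 40/80/160 min × decay 100/200/400 min) is run
  coarsely first, and the best start is polished at full precision
  (xatol 1e-4 in log-rate, i.e. ~0.01% in the rates).

Bounds separate the time scales: lambda_RNA half-life 60–3000 min, both
protein rates 30–1000 min. The fitting path contains no randomness — fixed
start grids, deterministic golden section — so repeated fits are identical.

Identifiability. Because k_trans is profiled exactly, the outer objective
is exactly symmetric under swapping k_mat and lambda_fluor; the swap is
resolved by convention: the faster of the two shared rates is reported as
maturation. This matches destabilized fluorescent reporters, whose
chromophore matures in tens of minutes while degron-driven decay takes
hours. Permutations involving lambda_RNA are broken structurally: lambda_RNA
is per-variant while the protein rates are shared, so any dataset whose
variants differ in mRNA stability pins the roles. Single-variant datasets
are fit but flagged non-identifiable.

Replicates are fit independently at the local level and aggregated
afterwards (mean and n−1 SD of half-life and production rate; SD = 0 plus a
flag for a single replicate), while the global level pools every
replicate's objective. An optional constant-background offset per curve is
available and off by default, since the assay's background treatment is
unspecified. Five-point luminescence grids can be fit with the same
machinery but leave little room per curve (2 local parameters from 5
points); the intended input is the 37-point fluorescence grid.

## Summaries and group comparison

AUC defaults to the plain sum of signal values over the sampled time points
— the convention used for the plate-reader totals this package mirrors —
with trapezoidal integration over minutes available and recommended
whenever time grids differ between variants; the method used is recorded.
Fold-changes divide each variant's mean AUC by the reference variant's,
per cell line.

Group comparison applies Shapiro–Wilk per group at alpha = .05; if every
group passes (the stricter reading of "the data passed", recorded in the
output so the gate can be audited), one-way ANOVA with Tukey's HSD follows,
otherwise Kruskal–Wallis with Dunn's post hoc. Dunn's test is implemented
here (rank z-statistics with tie correction) because no installed package
provides it; its adjustment defaults to Bonferroni, the conservative choice
when none is named. Significance is reported on the .05/.01/.001/.0001
ladder.

## Synthetic data

The generator emulates the study conditions the pipeline was built for:

* Cell-line presets: A549 — mRNA half-life 400 min, fluorophore half-life
  259 min; HEK293T — 350 min and 179 min. Fluorescence sampling every
  120 min from 300 to 4620 min (5–77 h); luminescence at
  240/960/1440/2880/4320 min. Maturation half-life defaults to 60 min, a
  typical value for red fluorescent reporters — the fits estimate this rate
  but no reference value exists for it, so the default is a generator
  convenience only.
* Default 10-variant panel: mRNA half-life multipliers log-symmetric in
  [1/1.4, 1.4] (median 1.000 to within 0.1%), reflecting the finding that
  tail segmentation barely moves mRNA stability, and translation rates
  spanning 1–6×, the observed range of total protein output. The multiplier
  spread also provides the between-variant contrast that makes the shared
  protein rates identifiable.
* Noise: mean-one multiplicative log-normal per well and time point with
  CV 0.05 by default — the error structure typical of fluorescence
  intensities, and it preserves positivity. Additive Gaussian noise and an
  optional per-replicate transfection-efficiency multiplier (off by
  default) are available. Three technical replicates by default.
* Reproducibility: one experiment seed drives a named substream per
  (variant, replicate) keyed by a CRC32 of the variant label, so adding
  variants never perturbs existing curves.
* Colony sets: each clone is intact/shortened/altered with stated
  probabilities; shortened clones delete a uniform number (≥1) of adenines
  from a uniform tract, redrawing the rare draws that would fully delete a
  tract between two spacers (whose merged spacers are ambiguous to label);
  altered clones substitute one spacer base or delete one spacer, falling
  back to a tract substitution for spacer-free references.

What the synthetic data do not emulate: image-level structure (cells,
segmentation), delivery kinetics, cell division, correlated
replicate-to-replicate variance, or any real sequencing error profile.
Passing recovery tests therefore shows the estimator is correct and
well-conditioned under the model's own statistical structure at realistic
noise, not that the model captures everything in live-cell data.

## Problem sizes and runtime

Recovery tests and the acceptance script use the full study-like condition
(10 variants × 3 replicates × 37 time points, 5% CV); one hierarchical fit
takes ~45 s on one CPU. The multi-seed recovery property (20 seeds) runs a
reduced condition — 4 variants × 2 replicates with a 2×2 outer start grid —
which the package treats as its standard small-sample benchmark; recovery
there is a few percent median error, comfortably inside the 10%/15% bands
asserted.

## Known limitations

* The shortened/altered distinction is sequence-exact; real Sanger traces
  with mixed or truncated reads need upstream cleaning.
* The grammar cannot recover A-containing spacers from a raw sequence (see
  round-trip note above).
* MAE objectives make the fit robust to outliers but the estimates carry no
  uncertainty beyond the replicate SD; no bootstrap or posterior is
  provided.
* AUC method "sum" depends on the sampling grid; comparisons across
  different grids should use the trapezoid method.
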