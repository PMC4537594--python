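# Methods

`ionpanel` re-creates, over synthetic data with known ground truth, the two
computational halves of an "indirect" blood-biomarker discovery program for
non-small-cell lung cancer: (1) label-free LC/MS quantitation across three
discovery platforms — resected tumor tissue, cultured cancer cell lines, and
serum-free conditioned medium — with differential-expression candidate
prioritization and multi-platform integration; and (2) serum verification
and multi-marker panel modelling on case/control cohorts. Because no raw
instrument data or subject-level concentrations accompany the study this
design follows, every input is simulated, and the published summary numbers
(per-platform candidate totals, overlap fractions, serum medians and IQRs)
serve as calibration targets rather than as re-derivable results.

## Synthetic proteomes and ion maps

A proteome is a set of random amino-acid sequences (vertebrate-like residue
frequencies, mean length 350). Each protein is digested in silico with the
trypsin rule (cleave after K/R, never before P; no missed cleavages), and
digest peptides of 5–25 residues are retained. A peptide is *observable* iff
it contains a cysteine or an N-glycosylation sequon N-X-S/T with X ≠ P —
mirroring the thiol-capture and hydrazide/PNGase-F enrichment chemistries
such programs rely on. A configurable fraction of proteins is "spiked" with
a tumor/control fold change (default 8×); the rest are null (fold 1).
Localization (secreted / cell membrane / other) is drawn independently of
spike status, so the localization filter is genuinely exercised.

Each observable peptide yields ions at charge 2 and 3 with theoretical m/z
(pyteomics monoisotopic masses), one reference retention time per peptide
(uniform on 5–115 min) and a base log2 intensity ~ N(20, 2). Per map the
simulator applies:

* a monotone quadratic RT warp `rt' = a + b·rt + c·rt²` (a ∈ ±2 min,
  b ∈ 0.95–1.05, c ∈ ±2·10⁻⁴ by default; strict monotonicity validated);
* an additive per-map log2 intensity offset (±1 by default);
* multiplicative log-normal noise, sd 0.25 on the log2 scale by default;
* left-censoring below a detection floor (2¹⁶, about 2 sd below the median
  intensity, censoring a few percent of ions per map);
* optionally, uniform random dropout. The default dropout rate is 0:
  in label-free feature data the dominant missingness mechanism is
  intensity-dependent censoring, and uniform dropout of bright ions would
  make the censored-ratio convention below (missing control ⇒ lower bound
  tumor/floor) systematically wrong. Dropout is kept as an explicit stress
  knob for missingness bookkeeping tests.

Twelve iRT-style internal-standard peptides with known anchor times are
spiked into every map; they receive the map's scale offset but neither
biological fold change, noise, censoring nor dropout, since they exist to
anchor the primary RT alignment. Cell-line and conditioned-medium
"platforms" are simulated with per-pair control draws of the same reference
sample rather than one physically shared control map — statistically
equivalent under this noise model and one code path for all platforms.

What the generator does **not** emulate: raw spectra, isotope envelopes,
chromatographic peak shapes, chimeric/contaminant ions, shared peptides
between proteins, missed cleavages, or intensity-dependent variance.
Passing tests therefore demonstrate the correctness of the alignment and
filtering logic under a clean feature-level error model, not robustness to
every pathology of real LC/MS data.

## Alignment

1. **Primary RT warp** — per map, an affine transform fitted by least
   squares to the internal-standard anchors (≥ 2 required).
2. **Secondary refinement** — iterative: *confident* features (m/z–charge
   blocks in which no map contributes more than one ion, present in ≥ 2
   maps; no RT gate, so arbitrary residual drift cannot hide features) are
   pooled, a per-map monotone piecewise-linear correction (11 knots by
   default) is fitted to the median residuals against the cross-map
   consensus RT, and the loop stops when the median absolute residual stops
   improving (≤ 5 iterations). Monotonicity is enforced at the knots, so
   within-map elution order is never permuted.
3. **Matching** — ions group across maps on identical charge, m/z within
   10 ppm and RT within 1.0 min (both config-overridable; the tolerances are
   package defaults, not published values). Candidate blocks are formed by
   single-linkage over sorted m/z; within a block, maps are visited in
   sorted order and each map's ions are assigned to existing groups by a
   rectangular linear assignment on the combined distance (ppm distance
   normalized by tolerance, plus an RT term down-weighted ×10⁻³ so m/z
   dominates and RT breaks ties); infeasible pairs open new groups. For two
   maps this is exactly the minimum-total-distance one-to-one matching, and
   the whole procedure is deterministic and input-order-independent.
4. **Intensity normalization** — one additive offset per map on the log2
   scale, minimizing the sum of squared deviations of each observed ion
   from its per-ion cross-map mean ("sum of differences" is read as squared
   log-scale deviation, the standard model for multiplicative MS intensity
   error; an L1/median variant is selectable). Solved by alternating
   closed-form updates (tolerance 10⁻¹⁰, ≤ 100 iterations), offsets centered
   to sum to zero, missing cells excluded rather than imputed. Normalization
   is computed per experiment (whatever set of maps the caller passes);
   grouping across platforms is the caller's decision.

## Candidate discovery

Tumor/control ratios are computed per identified feature per sample pair as
`2^(Δlog2)` on normalized intensities. A missing control yields a *censored
lower bound* — tumor intensity over the detection floor expressed on that
map's normalized scale; a missing tumor yields no record. The ion-level
screen keeps ratios strictly greater than 4 (boundary values excluded;
censored records pass only if the bound itself exceeds 4 — conservative,
but it keeps genuine on/off markers). Protein-level candidates aggregate
flagged peptides: distinct-peptide and distinct-sample counts, the pooled
median of flagged ratios (a per-sample-then-median variant would be a
one-line change; pooling matches how published marker tables combine
peptide-level ratios), and platform membership. The prioritization filter
retains proteins with ≥ 2 distinct differential peptides, ≥ 2 samples,
median ratio > 4 and secreted/cell-membrane localization, and emits a
per-criterion audit trail. The four criteria commute; raising the threshold
can only shrink the retained set.

## Platform integration

Candidates union across platforms into a membership table; the Venn
partition reports the seven exclusive region counts, per-platform totals
and fractions as round-half-up integer percents. The packaged 179-marker
membership fixture reproduces the published per-platform totals
(113 / 86 / 65), triple overlap 14 and conditioned-medium × cell-line
overlap 29 (read as including the triple overlap: 15 + 14). Those printed
counts leave the tissue pairwise overlaps underdetermined (only their sum,
42, is fixed); the fixture freezes the split 30 / 12 so that downstream
fractions are stable, and carries "resolved in the same cell line" for
9 of the 29 shared markers as metadata (per-line provenance is not
published, so it is not recomputed). The packaged annotation table is a
synthetic stand-in for a curated class/localization snapshot: 141 of 179
markers classified (79 %), class counts chosen so the classified subset's
round-half-up percentages are receptors 14, cell adhesion 14, hydrolases
13, defense/immunity 10, proteases 9, enzyme modulators 8, signaling 8.

## Serum cohorts

Marker concentrations are log-normal per group, calibrated from published
median/IQR summaries: location = ln(median), scale = (ln Q3 − ln Q1)/(2·z₀.₇₅).
One published control IQR has a lower quartile printed as 0.00 (values
below the assay's detection limit); its scale uses the upper half-spread
(ln Q3 − ln median)/z₀.₇₅ instead. This calibration reproduces the median
exactly and the IQR *width on the log scale* exactly; individual quartile
endpoints match only when the printed quartiles are log-symmetric.
Marker–marker correlation defaults to independence (only marginals are
published) and accepts any PSD matrix. Cases share a latent severity
variable (coupling 0.5) that also drives lesion size (log-normal, median
2.6 cm, sd 0.6, clipped to 0.8–12 cm), so a well-fitted panel score
correlates with nodule size by construction; 44 % of controls carry small
benign nodules (0.2–1.2 cm). Ages, sex ratios, pack-years, stage and
histology frequencies follow the published cohort demographics. Paired
serum/plasma values are generated with a log-scale matrix effect of
configurable sd (0 ⇒ perfect concordance).

## Panel modelling

Marker verification reports medians, linear-interpolation IQRs, the
two-sample Kolmogorov–Smirnov test (scipy, asymptotic p) and the
single-marker AUC. AUC uses the rank (Mann–Whitney) formulation with
midrank tie correction; ROC curves enumerate every distinct threshold;
sensitivity-at-specificity uses achievable operating points only (no
interpolation).

The panel is an elastic-net-penalized logistic regression of case status on
the nine marker concentrations (ng/mL, untransformed by default; a log
switch exists):

    NLL(β) + λ·[α·‖β‖₁ + (1−α)/2·‖β‖₂²],  intercept unpenalized.

Markers are standardized internally (penalties are scale-dependent) and
coefficients reported back on the concentration scale. Fits delegate to
scikit-learn's saga solver, whose objective equals this one with C = 1/λ;
λ = 0 uses an unpenalized lbfgs fit, and in the penalty-dominated all-zero
limit the intercept is set to its exact profile optimum, the logit of the
case prevalence. The mixing parameter α is not published; the default is
0.5 and `alpha_sensitivity` reports how the retained marker set changes
with α.

λ is selected by bootstrap resampling (default 10,000 draws, reducible):
each draw refits the λ path on the in-bag sample (warm-started, solver
tolerance 10⁻⁴ inside the loop, 10⁻⁸ for final fits) and scores the
out-of-bag subjects; the λ with the best mean OOB AUC wins, ties going to
the larger λ. Draws whose in-bag or out-of-bag side is single-class are
skipped and counted. All randomness flows from explicit seeds (including
the solver's internal shuffling), so identical seeds give identical chosen
λ and coefficients. The final model refits on the full training set at the
chosen λ; markers with exactly zero coefficient leave the panel. A
bootstrap validation helper implements Harrell's optimism correction
(refit per draw; apparent AUC minus mean optimism). Evaluation reports
overall AUC, case-versus-control-subgroup AUCs (e.g. nodule / no-nodule
controls), sensitivity at 90 % specificity, the Pearson correlation of the
panel score with nodule size, and per-marker serum/plasma concordance.

## Problem sizes used by the packaged runs

The analysis drivers use 300-protein proteomes, 4 pairs per platform, a
283-subject cohort and 1,000 selection draws. The recovery study in the
acceptance suite uses 500-protein proteomes over 10 seeds and the
calibration checks draw 100,000 subjects per group. These sizes were chosen
so each script is a short desk run while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The clinical accuracies of the original study (training, bootstrap-
  validated and independent-test AUCs) depend on unpublished subject-level
  data and are deliberately **not** acceptance targets here; the simulated
  cohort's panel AUC reflects the calibrated marginals plus the package's
  own correlation assumptions, not the real joint distribution.
* With independent marginals, nine markers and n = 283, the mean OOB-AUC
  curve is nearly flat at small λ, and the selected penalty sits well below
  the level (λ·α ≈ √(n·p(1−p))) at which soft-thresholding zeroes an
  *independent* null marker exactly; the acceptance suite's marker-exclusion
  check measures exactly this and currently fails by design of the
  conditions. Exclusion of a weak marker at the selected optimum emerges
  when that marker is *redundant* — correlated with stronger markers, as
  real serum markers are — or as the L1 share α grows (see
  `alpha_sensitivity`). The correlation matrix of the cohort generator is
  the knob to explore this.
* The matcher's incremental per-map assignment is exactly optimal for two
  maps and a good heuristic beyond; it does not solve the NP-hard
  multi-dimensional assignment.
* Censored ratio bounds assume missing controls are genuinely below the
  detection floor; under uniform random dropout (off by default) they can
  overstate fold changes.
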