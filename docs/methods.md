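# Methods

This note documents the quantification model, the synthetic-data forward
model, the numerical choices and the known limitations of the package. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Quantification model

### Protein-directed track

Input is a PSM-level TSV (one `intensity_<label>` column per TMT channel;
channel semantics come from a YAML design mapping each label to a role —
`dmso_control`, `dmso_plus_alkyne`, `competitor_plus_alkyne`,
`compound_only` — a compound, a stereoisomer and a replicate index).
Processing order:

1. **Fractional ratios.** Each PSM's channel intensities are divided by
   their total over included channels. Missing cells (distinct from true
   zeros) do not contribute to totals; zero-total PSMs are dropped with a
   logged reason.
2. **Quality cascade** (strict `<` thresholds): summed reporter intensity
   < 10,000, signal-to-noise < 1.0, isolation purity < 0.5. Every dropped
   PSM is logged with all rules that fired. Missing purity/S-N metadata
   passes with a warning by default (strict mode available) since some
   export dialects omit these fields.
3. **Roll-up and normalization.** Per-protein channel signal = sum of PSM
   fractions. Signals are normalized to sum to 100 over the plex. When a
   design channel is excluded (e.g. a failed channel), its replicate
   partner — the lowest-replicate surviving channel of the same condition —
   is temporarily duplicated inside the normalization total and then
   removed, so the remaining channels sum to 100 minus the partner's
   normalized value and the plex stays balanced. Proteins with fewer than
   two distinct peptides are flagged `excluded_low_evidence`.
4. **Replicate screen.** Condition = (role, compound). CV = sample s.d.
   (ddof = 1) / mean over replicate channels. A protein is excluded when CV
   ≥ 0.2 in its most enriched DMSO+alkyne condition, chosen **per protein**
   by replicate mean (ties broken by declaration order); whether that choice
   should instead be fixed per experiment is ambiguous, and the per-protein
   reading is flagged here as an interpretation. Single-replicate conditions
   have undefined CV and are retained with `cv_warning`.
5. **Selectivity and classification.** Enrichment of a stereoprobe is the
   replicate-mean normalized signal of its DMSO+alkyne condition.
   Enantioselectivity is the enrichment ratio between declared enantiomers;
   a zero denominator is capped at a configurable ceiling (default 100) and
   flagged `es_saturated`, keeping quadrant-plot coordinates finite.
   Diastereoselectivity divides by the arithmetic mean of the two declared
   diastereomers. Competition (%) = 100·(1 − competitor-condition mean /
   matched alkyne-condition mean), floored at 0 and capped at 100 for
   reporting with the raw value retained — negative competition is noise,
   and reported percentages are bounded. Liganded requires, for at least
   one stereoprobe, enantioselectivity **strictly** > 2 and competition
   **strictly** > 50% — satisfied either in the protein track or by matched
   cysteine-track site competition (both routes accepted; the used route is
   recorded in `evidence_route`). Manual review is replaced by an automated
   `variability_flag` (any contributing condition CV ≥ 0.2) that is reported
   and never silently applied.

### Cysteine-directed track

1. **Engagement ratios.** Channel intensity / mean of the (≥2) DMSO-control
   channels; the mean DMSO ratio is 1 by construction. Zero-DMSO PSMs are
   dropped with a logged reason.
2. **Site roll-up.** Probe-labeled residues are identified from the
   +398.25292 Da (±0.01) IA-DTB modification and mapped to 1-based protein
   coordinates through `peptide_start`. PSMs with more than two labeled
   residues are rejected; doubly labeled peptides are reported jointly under
   a combined key (e.g. `C212_C220`) since the positional isomers are not
   resolvable from reporter intensities alone. PSM filters: summed DMSO
   intensity < 10,000 excluded; DMSO CV > 0.5 excluded (both strict).
3. **Dispersion screen.** The published rule "mean absolute deviation or
   mean > 0.2" is ambiguous: read literally, excluding sites whose mean
   ratio exceeds 0.2 would remove essentially every site (ratios center on
   1). The default implementation excludes a site whose DMSO-condition
   ratios have mean absolute deviation > 0.2; the literal reading is
   available behind `literal_mean_rule` and the choice is recorded in the
   profile columns rather than guessed away silently.
4. **Classification.** Site competition = 100·(1 − replicate-mean ratio)
   per compound. Site enantioselectivity has no published formula for
   decreases; it is implemented as the ratio of competition complements,
   (1 − r_active) / max(1 − r_enantiomer, ε) with ε = 0.01 and a cap of 100
   — the natural reading that stays numerically stable when the enantiomer
   is inert. A site is liganded at competition > 50 and enantioselectivity
   > 2 with a unique peptide and supporting evidence: the protein passed
   protein-directed liganding (`protein_track_support`) or another
   quantified peptide of the protein shows no liganding
   (`sibling_peptide_support`); otherwise `insufficient` — distinguishing
   engagement from protein-abundance changes.

### Complexoform discordance

All competition quantities enter as fractions. Each liganded protein is
matched to its **best-competing** quantified site — the presumptive
probe-modified cysteine. Flat sibling sites are deliberately not candidate
signatures: a cysteine far from the binding site shows no competition even
for an ordinary target, so treating every site as a candidate would flag
nearly every multi-site protein. The pair is flagged when c_protein ≥ 0.5
and D = c_protein − c_site ≥ 0.3 (both configurable); f̂ = c_site/c_protein
is clamped to [0, 1] with a saturation flag. `estimate_fraction` exposes the
same quotient for direct whole-pool vs complexed-pool engagement readouts
(e.g. paired IP-MS), refusing estimates when the complexed-pool readout is
below 0.25 (unstable quotient) and propagating input CVs by a first-order
delta method under cross-track independence (the tracks are separate
experiments; no covariance is available).

The underlying assumption — the scout probe reacts with the site in every
complexoform while the elaborated stereoprobe reacts in only one — is a
model, not a validated fact; the package implements it as stated and cannot
test it from ABPP data alone.

### Comparative cross-state regression

Per-protein stereoselective enrichment ratios (probe-B/probe-A) in two cell
states are compared by OLS on log2 scale, two-pass: fit all shared proteins,
flag externally studentized residuals beyond 3 (plus any prior-knowledge
exclusion list), refit without them. A data-driven rule replaces
named-protein exclusion so the procedure is reproducible on new datasets;
the prior list preserves the knowledge-driven override. Degenerate
(perfectly colinear) first passes yield no outliers. Fewer than 3 shared
proteins refuses the regression.

## Kinetics

All fits are nonlinear least squares (`scipy.optimize.curve_fit`, tolerances
1e-10, ≤10,000 evaluations) seeded from deterministic linearizations:
log-linear regression for decay, the dose nearest 50% response (Hill slope
1) for the IC50, Lineweaver–Burk for Michaelis–Menten. Confidence intervals
are symmetric Wald intervals (±1.96 SE); lower bounds are reported even when
negative. Inputs are SI (seconds, molar); the CLI requires explicit unit
columns and converts, so µM/mM mixing cannot occur silently.

* **First-order decay** v(t) = v₀e^(−kt), with v₀ either fitted or fixed at
  1 (both supported because it is unstated whether single-endpoint rates
  should reference the nominal or the measured initial concentration).
  Traces where nothing falls below the initial observation return k = 0 with
  a `no_decay` flag. k_obs/[I] (M⁻¹s⁻¹) is derived when [I] is declared.
  The single-endpoint closed form −ln(v)/(t·[I]) equals a two-point
  v₀-fixed fit; complete consumption (v ≤ 0) is an explicit undefined
  status, never a fabricated rate.
* **Constrained 4PL**: response = 100/(1 + (IC50/x)^h) with top/bottom fixed
  at 100%/0%, parameterized as (log10 IC50, h) for stability. Data never
  crossing the transition (all responses > 75% or < 25%) return a
  `no_transition` status with no fabricated IC50; falling responses trigger
  a `non_monotonic` warning but the fit is still attempted.
* **Michaelis–Menten** over pooled replicates; k_cat = V_max/[E];
  k_cat/K_m CI by Wald propagation of the joint (V_max, K_m) covariance.
  K_m beyond 10× the largest substrate concentration attaches an
  extrapolation warning. An optional additive basal-rate parameter (off by
  default) absorbs cofactor-independent background activity such as
  copurified cofactor turnover, in which case fitted parameters should be
  reported as apparent values.

## Synthetic-data forward model

The generator emulates the structure of the two experimental tracks, not
their physics. Defaults define the study conditions used throughout the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 200 | proteins per dataset |
| psm_per_protein | 8 (Poisson) | PSMs per protein (split over sites in the cysteine track) |
| base intensity | log-normal, median 5·10⁴, log-sd 1.0 | per-channel reporter scale of a quantifiable protein/site |
| liganded_fraction | 0.10 | planted stereoselective targets |
| planted_competition | 0.80 | competitor blockade of the active probe |
| planted_enantioselectivity | 4 | active:enantiomer enrichment ratio |
| replicate_cv | 0.10 | per-(protein, channel) log-normal replicate effect |
| psm_noise_sd | 0.10 | per-(PSM, channel) log-normal measurement noise |
| interference_level / prob | 0.3 / 0.2 | co-isolation mixing weight and affected-PSM fraction |
| missing_rate | 0.05 | PSM dropout |
| background_binding | 0.05 | DMSO-control bead background (protein track) |

Reporter intensities factor as abundance × planted channel expectation ×
replicate effect × PSM factor × channel noise, all log-normal, so with every
noise term at zero the downstream pipeline reproduces each planted quantity
to machine precision (asserted in the tests). Co-isolation interference is
convex mixing of a PSM's channel vector with a flat background profile with
weight w; `isolation_purity` is recorded as 1 − w, which ties the purity
filter to an actual, detectable distortion: at w > 0.5 the affected PSMs
fall below the purity threshold and are exactly the ones removed. At the
default w = 0.3 the affected PSMs *pass* the filter and compress ratios
toward the background — deliberately, because that is the real failure mode
isobaric quantification suffers below the filter threshold. This compression
is the dominant error term in site-engagement estimates (MAE ≈ 0.04 at
defaults) and produces occasional per-target track discordance of up to
~0.1 even without complexoform restriction, which is why track-consistency
is asserted on the central tendency and the discordance flag requires
D ≥ 0.3.

The base-intensity scale is chosen so that quantifiable sites sit comfortably
above the 10⁴ summed-intensity floor (as confidently quantified TMT peptides
do) while the low-abundance tail still exercises the filter; peptide
sequences are random with protease-consistent C-termini (trypsin: K/R;
Glu-C: D/E) so the site-mapping path, including Glu-C digests, is exercised.
Seeding uses `numpy.random.default_rng(seed)` exclusively; identical seeds
yield byte-identical TSV output.

In the complexoform scenario the protein- and cysteine-track datasets are
generated from the same seed so the planted target sets and active
stereoisomers coincide (stereomatched across the alkyne/competitor compound
pairs); planted expectations are c_protein = e and c_site = f·e.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatographic and spectral artifacts, isotope
envelopes, peptide-specific ionization efficiency, shared (non-unique)
peptides and protein-inference ambiguity, correlated interference from
co-eluting peptides (the background here is flat and uncorrelated), protein
abundance changes confounding competition, and the accuracy of upstream
search/FDR. Recovery rates measured here are upper bounds relative to real
experiments.

## Problem sizes used

The default test run and the acceptance script use 200-protein datasets,
20 seeds for ligand-recovery rates, 8 seeds for reactive-fraction recovery,
20–50 seeds for flag calibration and 50 replicate fits for the kinetic
recovery distributions — sizes at which the measured rates are stable to a
few percent while the whole suite completes in a few minutes on one CPU.

## Known limitations

* Protein identity is the accession string: no protein grouping, isoform
  collapsing or parsimony inference.
* No FDR estimation; inputs are assumed to be search-engine output already
  filtered upstream.
* Positional isomers on doubly labeled peptides are reported jointly, not
  resolved.
* The discordance flag conflates complexoform restriction with any
  mechanism that suppresses site-level competition relative to
  protein-level competition (e.g. an undetected second liganded site on a
  nonproteotypic peptide); flagged pairs are candidates for orthogonal
  follow-up, not proofs.
* Wald (symmetric) confidence intervals only; profile-likelihood intervals
  are out of scope.
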