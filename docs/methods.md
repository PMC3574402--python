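# Methods

This note records the models, conventions and design choices behind
`varzea`, in the order the pipeline applies them.

## Data model and season calendar

A survey is a long table of *detection* records over
(lake, year-month, sampling unit, species) with a positive individual count
and a positive summed wet mass in grams. Absence is implicit: zero-count
rows are rejected rather than stored, so every occupancy quantity downstream
is defined purely by detections. A record's biomass is the summed wet weight
of its individuals; individual fish are not modelled as separate rows.
Species and lake identifiers are opaque, case-sensitive strings.

The hydrological year is split into four seasons. The natural boundaries are
mid-month (high water runs into mid-July), which a month-resolution calendar
cannot honour, so the default calendar rounds to whole months: May–July
*cheia*, August *vazante*, September–November *seca*, December–April
*enchente*. The calendar is total (every month maps to exactly one of
exactly four labels) and fully overridable. Seasons pool across calendar
years — October of any year is *seca* — which is what bounds the temporal
persistence covariate to 1–4; a year-specific season would make that range
impossible. The data model accepts any set of months and does not insist on
a particular survey span; the default synthetic layout uses 19 consecutive
months starting in a September.

## Abundance structure

Abundance is measured in two currencies, individuals and grams, through the
same code paths. SAD histograms use half-open decade classes
[10^k, 10^(k+1)) with k any integer, so sub-gram biomass totals fall in
negative classes; the binning convention (rather than, say, base-2 octaves)
is a package choice since only the base-10 classing of the analysis is
fixed. The common/rare split applies a strict "less than" rule at the
threshold (default 1% of all individuals): a species at exactly the
threshold is common. The split is defined on the individuals currency by
default but the currency is a parameter. Rank-abundance ties are broken
lexicographically by species identifier so curves are deterministic. No
changepoint or "inflection" detection is performed on the rank-abundance
curve — the operational rule is the threshold — and no lognormal or
veil-line model is fitted to the SADs.

## Occurrence

A species' spatial occurrence is the number of distinct lakes with at least
one detection, ever; temporal occurrence is the number of distinct season
labels, pooled across years. Occupancy is detection-based with no abundance
weighting. The joint occurrence distribution is tallied on the full
1..L × 1..T grid; its two modal cells (ties broken toward the smaller cell
index) summarise the core–satellite split. SAD deconstruction groups
species by their raw integer occurrence level — no binning of levels — and
conserves the plain histogram exactly by construction; the package still
asserts the identity on every run. No formal bimodality statistic is
computed and no spatial autocorrelation is estimated.

## Rarity status

Rare species are classified against a reference table of
(species, habitat, present, within-habitat relative abundance) over a
declared set of other habitat types (canonically six). Under a definition
(min habitats m, optional share threshold t), a rare species is rare
locally iff it is present in ≥ m habitats, or t is set and its share
reaches t in at least one habitat where it is present; otherwise rare
throughout. "Share when present" is read per-habitat — the species' share
of the habitat's own total, maximised over habitats where it occurs —
because the phrase scopes the share to the place the species is present. An
alternative pooled reading (share of the summed regional total, approximated
as the per-habitat sum divided by the number of habitats, i.e. assuming
equal habitat totals) is available as `share_mode="pooled"`. Rare species
with no reference rows at all carry no regional information and are
*excluded*, never defaulted to rare throughout. Habitats where a species is
absent contribute nothing, and classification is invariant to row order.

The four shipped definitions — (i) m=2; (ii) m=3; (iii) m=2 or t=0.005;
(iv) m=2 or t=0.01 — are logically nested: RL(ii) ⊆ RL(i) because m=3
implies m=2; RL(i) ⊆ RL(iv) ⊆ RL(iii) because an OR clause only adds
members and a 1% share implies a 0.5% share. `check_definition_nesting`
asserts the chain on every dataset; a violation can only be an
implementation bug, so the report names offenders rather than soft-failing.

## Logistic regression and tests

The response codes rare throughout as 1 and rare locally as 0; excluded and
common species never enter. Predictors are log10 mean wet weight in grams
(from the traits table when present, else total biomass over total count)
and one persistence factor — lakes or seasons, never both in one model and
no model selection across the two. Factors are treatment-coded with the
lowest *observed* level as reference; an unobserved level gets no column
and the Wald degrees of freedom shrink accordingly (reported in the model
output).

Fitting is Newton–Raphson/IRLS written in the package: score X′(y − μ),
observed information X′WX with W = diag(μ(1−μ)), weights floored at 1e-12,
and a step-halving safeguard (up to 30 halvings) so the log-likelihood
never decreases. Convergence requires both the score sup-norm and the
relative step sup-norm below 1e-8 within 50 iterations. Coefficients
passing |β| > 15 while the likelihood still improves raise a separation
flag and stop the fit: under (quasi-)complete separation the MLE does not
exist and reporting a flagged, unconverged fit is the honest outcome. The
covariance is the inverse observed information at the optimum. The test
suite cross-checks coefficients, standard errors and log-likelihood against
an independent GLM implementation and against the closed-form saturated
2×2 logit.

The joint Wald test of a factor is χ² = b′(V_bb)⁻¹b over the dummy block
with df equal to the block size; its p-value is the regularized upper
incomplete gamma Q(df/2, χ²/2), accurate to well below 1e-10 (checked
against the df=2 closed form exp(−x/2) and a quadrature oracle). The
interaction screen is a likelihood-ratio test of nested designs with and
without weight × dummy columns. Predicted-probability surfaces are the
inverse logit of the linear predictor over a body-size grid at each
observed factor level, and are refused for unconverged fits.

## Synthetic communities

The generator emulates the study design at desk scale: 5 lakes × 19 months
× 5 units of 16 m², with a two-pool species model.

* **Core pool** (30 species): occupies every lake and season (inclusion
  probability 1.0 by default, adjustable); per-unit detection intensity λ
  lognormal, log10 λ ~ N(0.15, 0.35).
* **Satellite pool** (250 species): log10 λ ~ N(−1.85, 0.6); each species
  occupies one home lake and season plus extras drawn with probability
  expit(α + βz) where z is its standardized log-intensity (lakes:
  α=−1.1, β=0.9; seasons: α=−0.9, β=0.9). This intensity–occupancy coupling
  is what produces the occupancy–abundance relationship.
* **Counts** per unit are negative-binomial with size k=0.6: fish aggregate
  within floating meadows, and a Poisson would under-disperse relative to
  the heavy singleton excess the count SAD must show.
* **Body mass** log10 ~ N(0.4, 0.65) grams; record biomass is
  count × mass × lognormal noise (σ=0.12).
* **Truth labels** are assigned from generative parameters, never from the
  realized sample: core species are common; a satellite is rare locally
  with probability expit(logit(0.45) + 1.0·z), else rare throughout. The
  slope couples regional status to intensity, so persistence is genuinely
  informative about status — the effect the inference stage exists to
  detect. (The marginal rare-locally fraction is thereby pulled slightly
  toward 0.5 relative to the 0.45 anchor; the difference is immaterial.)
* **Reference habitats**: with consistency c (default 0.9), a
  truth-rare-locally species receives the canonical rare-locally signature
  (present in 2 + Binomial(4, 0.35) habitats, shares Beta(1.2, 60)) with
  probability c and the rare-throughout signature otherwise; vice versa for
  truth-rare-throughout (present in at most one habitat, share uniform
  below 0.0045, i.e. under every threshold). At c=1 classification under
  definition (i) recovers truth exactly; at c=0.5 recovery is at chance.
  2% of non-common species carry no reference rows and end up excluded,
  emulating incomplete regional information. Core species get broad,
  high-share reference profiles; a core species that realizes below the 1%
  survey threshold is therefore classified rare locally — which is the
  correct description of a regionally common species that happened to be
  scarce in the focal habitat.

Defaults were chosen once, when the generator was designed, to make a
default run "look like" the emulated study: ~175 realized species, ~25 000
individuals, ≥ 20% singletons, count-SAD mode in the lowest decade,
unimodal lognormal-like biomass SAD, and joint-occurrence modes at (1,1)
and (5,4). Identical (config, seed) gives byte-identical output at every
stage.

What the generator does *not* emulate: hydrological dynamics and
within-season water-level effects on catchability, spatially explicit lake
geometry or inter-lake distance, individual movement, and any trait
structure beyond body mass. Passing tests on these communities show the
pipeline's statistical machinery is correct and well-calibrated under a
realistic abundance/occupancy regime; they cannot certify behaviour under
field pathologies the generator omits (gear selectivity, misidentification,
detection covariates).

Small default simulations occasionally yield quasi-separated lakes models
(few rare species realized in 4–5 lakes, all of one status); the fitter
flags these rather than papering over them.

## Experiments and problem sizes

`recovery_experiment` runs the full pipeline per replicate and scores
classification accuracy against truth over species that are truth-rare,
realized-rare and not excluded. `wald_coverage_experiment` draws
known-coefficient rare-species tables (default n=400: log10 weight
~ N(0.4, 0.65), season levels with probabilities 0.4/0.25/0.2/0.15, true
coefficients intercept 0.4, weight −0.8, season contrasts −0.6/−1.1/−1.6),
refits, and reports per-coefficient and pooled 95% interval coverage; 200
replicates put the pooled estimate within about ±0.015 of the true level.
The test suite exercises the nesting invariant on 120 hypothesis-generated
datasets, conservation on 10 simulated surveys in both currencies, and
structural fidelity on 100 seeds; these sizes keep the whole suite under
half a minute while leaving the majority-based checks far from their
decision boundaries.

## Pipeline and reproducibility

`run_pipeline` writes all artifacts as delimited text or JSON and finishes
with a manifest of SHA-256 hashes; the manifest is written last so a failed
run is recognizable by its absence. Logs record stage summaries (counts,
test statistics) and no wall-clock timings, so a rerun with the same config
and seed reproduces every hash bit-for-bit. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; replicate seeds
are spawned via `SeedSequence` so experiments are reproducible and
non-overlapping.
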