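# Methods

This note documents the models, rules and numerical choices behind the
pipeline, in the order the stages run.

## Data model and units

A well holds one embryo.  Mortality is recorded at 24 and 120 hpf and is
treated as absorbing: an embryo dead at 24 hpf is dead at 120 hpf, and a
record claiming otherwise is an invariant violation.  Phenotype flags are
defined only for embryos alive at 120 hpf (scoring happens on survivors);
dead embryos carry *not assessed* (empty) cells in the wells CSV.
Concentrations are stored in µM as dosed and converted to log₁₀ molar only
at analysis boundaries (`log10_molar(c) = log10(c·10⁻⁶)`), because dosing
is specified in µM while potencies are compared in log₁₀ M.  Well
positions are opaque labels; plate-map geometry (which wells hold VC) is
configuration, not schema.

Two built-in plate designs fill a 96-well plate exactly: 7 test
concentrations × 11 embryos, or 11 × 7, each plus 12 VC wells and 7
single-embryo PC wells.

The relational DDL export targets generic ANSI SQL.  Because one well
holds many phenotype observations, the `well` table carries foreign keys
to `screen_plate` and `dose`, and links to `recording` through a
one-row-per-observation child table `well_phenotype`; the loader writes
one child row per assessed flag.

## Endpoint construction

For endpoint kind *combined*, the per-concentration numerator is
(dead at 120 hpf) + (alive with the recording flagged); for *mortality*,
deaths at the endpoint's timepoint; for *any-malformation*, dead or any
**binary** recording flagged — binarized quantitative traits (thresholded
continuous measurements such as trunk length) are excluded because mixing
them in produces non-monotone responses.  Denominators are all embryos
dosed at the concentration.  Concentrations with zero embryos are dropped,
not imputed.  A lab with *n* recordings therefore generates *n* + 2
endpoints at 120 hpf; `Mortality@24` exists separately for QC.

PC wells carry one embryo per concentration per plate, so PC curves pool
plates run in the same ISO calendar week (a reproducible grouping; a
sliding 7-day window would be an alternative but makes pools depend on
scan order).  A pool with a single plate is flagged `low_n`.

## Curve correction and BMC

Responses are first baseline-anchored by subtracting the plate's own VC
response for the same endpoint, floored at 0 (toggleable,
`anchor_baseline`); the BMR thresholds are interpreted as levels above
baseline noise, so curves should start near zero.  The noise correction
is a weighted least-squares isotonic (non-decreasing) projection, weighted
by per-concentration embryo counts and clipped to [0, 100].  Isotonic
projection was chosen as the monotone-curve-processing stage because it is
deterministic, assumption-light, and exactly testable against a
brute-force level-set oracle; reproducing any particular screening
package's sweep heuristics is a non-goal.

The BMC at benchmark response *t* is the log₁₀-molar concentration where
the corrected curve first reaches *t*, linearly interpolated between the
bracketing tested concentrations.  Boundary rules: a curve already at or
above *t* at the lowest tested concentration returns that concentration
(`censored_low`); a flat corrected segment exactly at *t* resolves to the
segment's lowest concentration; a curve never reaching *t* is inactive and
substitutes the highest tested concentration in downstream variance and
specificity computations (`censored_at_max`).

## BMR selection

For each endpoint, candidate thresholds 5%…95% in 5% steps (default) are
scanned; at each, BMCs are computed for all substance × replicate curves
and pooled into s²(t) = Σ(nₛ−1)s²ₛ / Σ(nₛ−1) over substances with ≥ 2
replicates, censored values substituted for inactives.  Whether the
original pooling used only substances active at each threshold is not
determined; substitution was chosen for consistency with the SD
convention used in the variability summaries.

"Stabilised" is instantiated concretely: fit v(t) = a·e^(−kt) + c and take
the smallest grid threshold with v(t) ≤ c + 0.05·a (5% of the decay
amplitude above the asymptote; `tol` configurable).  The fit uses only the
decaying phase of the profile, up to its minimum: at very high thresholds
most curves go inactive and the substituted censored values drive the
pooled variance back up, which reflects the substitution rule rather than
potency instability.  Degenerate profiles degrade gracefully: flat →
already stable, BMR = lowest threshold; never-decaying or unfittable →
`converged = False` with the highest threshold and a warning, never an
exception.

## Specificity

Score = BMC(mortality) − BMC(phenotype) per plate, both at 120 hpf.  When
mortality is inactive its censored maximum-concentration value is used, so
a phenotype active below an entirely non-lethal range earns a large
positive score.  The cutoff is −Q₀.₀₅ of the dataset's negative scores
(linear-interpolation quantile, h = (n−1)p), mirrored to a positive
number: negative scores are impossible under the counting model (dead
embryos count in every combined endpoint), so their distribution estimates
the noise of the BMC calculation, and mirroring its 5th percentile bounds
the false-specific rate near 5% under symmetric noise.  Classification:
specific (score strictly > cutoff), non-specific (≤ cutoff), non-toxic
(endpoint inactive).  Substance-level calls take the majority class
(> 50% of plates) with the mean BMC and mean score of that class's plates;
no majority → inconclusive, reporting the specific-class summaries if any.
Blinded duplicates are aggregated per blinded code, never merged across a
pair.

## Ontology collapse

The mapping table (CSV: `lab,recording,ontology_id,term_label,
granular_group,general_group`) encodes recording → term (many-to-many),
term → granular group (≤ 1), granular → general (exactly 1, validated).
Terms describing no structural change carry no group and emit no group
edges.  Collapsing a defect group takes the highest-precedence class
present (specific → non-specific → inconclusive → non-toxic) and, within
it, the most potent (numerically smallest) log₁₀ BMC; the operation is
idempotent.  The bundled `data/ontology_map_partial.csv` is an
illustrative partial table covering the widely shared terms and a
composite (one-to-many) recording; complete studies supply their own.

## QC

Vehicle control: per plate, `Mortality@24`, `Mortality@120` and
`MalformedAny+Mort@120` responses fail only when strictly above 20%
(exactly 20% passes).  Flags never remove data — marginally failing plates
are a judgement call for the analyst — but `strict_qc` optionally excludes
failing plates from analysis.  PC reproducibility: sample SD (n−1
denominator throughout; the convention is not otherwise pinned down) of
weekly-pool BMCs per endpoint, with 10^SD fold equivalents and the median
across endpoints.  Duplicates: per endpoint, |median₁ − median₂| of the
triplicate BMCs of the two members, flagged above 0.5 log₁₀ (~3.2-fold);
identical medians stay in the table but are excluded from the concordance
plot output.  Endpoint variability: per substance × endpoint triplicate
SD with censored substitution; only SD > 0 rows (active in ≥ 1 run) enter
distribution summaries.

## Synthetic studies

The generator's defaults are the study conditions: 41 blinded test
substances (35 singletons + 3 duplicate pairs sharing ground truth under
different codes) plus one PC, screened in triplicate on separate dates by
three labs — Lab-A (7 × 11, static-renewal/chorion, 21 binary recordings,
0.5 log₁₀ spacing), Lab-B (11 × 7, static/dechorion, 9 binary recordings,
0.2 log₁₀ spacing), Lab-C (7 × 11, static/chorion, 12 binary + 9
binarized-quantitative recordings, 0.5 spacing) — with a maximum
concentration of 100 µM.  Mortality AC50s are log-uniform over 1–500 µM
(so some substances are inactive in range), Hill slopes 2–6; each
substance affects each recording with probability 0.35, with phenotype
AC50 shifted 0.1–0.8 log₁₀ below mortality.  VC baselines: 4% mortality by
120 hpf everywhere; any-malformation baseline 8% (Lab-A/B) and 15%
(Lab-C, the elevated-baseline lab), divided evenly across binary
recordings assuming independence.  These magnitudes were fixed once as
representative of embryo screens of this kind.

Death by 120 hpf is a Bernoulli draw from the mortality Hill curve; a
fixed 40% of deaths occur by 24 hpf; phenotypes are drawn only for
survivors, which makes the combined endpoints monotone in expectation.
Each plate derives its RNG from the global seed plus a CRC32 of the plate
id, so any plate is reproducible in isolation and `simulate_study` is
byte-identical under a fixed seed.

What the generator does **not** emulate: correlated phenotypes within an
embryo (flags are conditionally independent), concentration-dependent
scoring error, inter-plate drift beyond the seeded draws, non-monotone
true responses, or solvent/handling artifacts.  Tests passing on
synthetic data therefore demonstrate the pipeline's correctness and
statistical behaviour under its own model assumptions, not performance on
any particular laboratory's real data.

## Problem sizes and runtimes

The full-scale end-to-end check runs 3 labs × 41 substances × 3 plates
(≈ 35 000 wells per lab) through simulation, endpoint construction, BMR
scans over 19 thresholds × 57 endpoints, BMC fitting, QC, specificity and
collapse in well under a minute on a single core; unit and property suites
use reduced studies (6–8 substances) and hand-built plates.  Statistical
tests use seeded generators and Monte-Carlo tolerances stated inline.

## Known limitations

- The isotonic correction is a deliberate, documented stand-in for
  screening-specific noise-sweep algorithms; absolute BMC values can
  differ from pipelines using those, though the monotone-POD intent is the
  same.
- The stabilisation criterion (exponential fit, 5% amplitude) is one
  concrete reading of "lowest stable threshold"; profiles that never decay
  select the highest threshold un-converged rather than guessing.
- The bundled ontology table is partial and illustrative; cross-lab
  overlap statistics on it are format demonstrations, not findings.
- Mean terms-per-recording ratios are reported exactly and rounded
  half-even in displays.
- No bootstrap confidence intervals on BMC; replicate spread is summarised
  by SD only.
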