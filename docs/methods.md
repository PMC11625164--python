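# Methods

`hmrisk` implements a deterministic dietary exposure and health-risk
assessment for trace metals in fish muscle, of the kind used to evaluate
consumers of fish from contaminated rivers. The shipped reproduction
profile describes a survey of four species from the Dhaleshwari River
(Bangladesh) — one carnivore (*Wallagu attu*), two omnivores (*Ompak
bimaculatus*, *Labeo calbasu*), one herbivore (*Cirrhinus mrigala*) —
sampled in dry and wet seasons and analysed for Cr, Pb, Cu, Cd and As.

## Exposure model

For a consumer scenario with intake rate FIR (g/day), body weight BW (kg),
exposure frequency EFr (days/year), duration ED (years) and averaging time
TA (days), and a mean wet-weight tissue concentration Cm (mg/kg):

    EDI = (EFr · ED · FIR · Cm) / (BW · TA) · 10⁻³    [mg/kg/day]
    THQ = EDI / RfD
    HI  = Σ THQ over co-occurring metals
    TR  = EDI · CSF

The 10⁻³ converts FIR from grams to kilograms. For chronic lifetime
scenarios TA = EFr·ED, so the scenario factor is exactly 1; the engine
computes it rather than assuming cancellation, so sub-lifetime scenarios
remain expressible. The model assumes complete gastrointestinal absorption
and no cooking losses; only the ingestion route is assessed (no dermal or
inhalation pathways).

Classification: THQ and HI are compared to the threshold 1; TR is banded
at the USEPA markers 10⁻⁶ and 10⁻⁴. The sources state the bands as strict
inequalities, leaving the boundaries unassigned; both boundaries are
placed in the middle ("tolerable") band — conservative at the lower edge,
lenient at the upper — and the constants live in `risk.py` as named module
attributes. Metals without a CSF (Cu, an essential element) are excluded
from TR by the absence of the constant, not by name, so the rule
generalises to other metal panels. PTDI comparison uses strict inequality;
equality is compliant.

## Concentration handling

Measurements arrive as sample-level records (species, season, metal,
value, dry/wet basis, censored flag, detection limit). Processing order
fixes the estimand:

1. **Censoring substitution.** A below-detection record is replaced by
   half its detection limit (LOD/2), the standard simple substitution for
   left-censored trace data. The Cd limit is the LOD 0.1 mg/kg dw (the
   LOQ 0.2 is carried separately in config, labelled as such); As uses
   LOD 0.002 mg/kg dw.
2. **Basis conversion.** C_ww = C_dw · (1 − moisture_fraction), with the
   per-species moisture from the profile table. The analyte mass is
   unchanged while the reference mass gains the tissue water, so wet
   weight never exceeds dry weight.
3. **Aggregation.** Arithmetic mean per species × metal × season; the
   across-season ("pooled") value is the **unweighted mean of the two
   seasonal means**, not the grand mean of replicates — this matches the
   survey's across-season averaging and coincides with the grand mean when
   replicate counts are equal.

The `as_uniform_ww` switch replaces every As summary (and the As column of
the replicate-level table feeding the stats stage) with a single
wet-weight constant, 2.0·10⁻⁴ mg/kg. The surveyed study carried one
substituted As value for all species despite differing moisture; the
engine's default is the per-species conversion, and the switch — on in the
reproduction profile — reproduces the published tables. With it set, the
forward-computed adult As EDI is 2.25·10⁻⁷ against a published 2.26·10⁻⁷,
i.e. agreement at ±1 in the third significant figure.

Guideline comparison is per configured authority–metal pair (mg/kg ww);
equality with a limit is compliant, unconfigured metals are not judged.
The shipped limits are literature food-safety constants and are the one
part of the profile not anchored to printed numbers.

## Inferential stage

- **Inter-metal correlation**: pairwise Pearson r over the replicate-level
  wet-weight values pooled across species, seasons and replicates, with
  two-tailed p from the t-transform at n−2 df. A metal left constant by
  censoring substitution has zero variance; its cells are reported as
  undefined with a `constant_input` flag rather than dropped or erroring,
  mirroring how survey correlation tables footnote such columns. Rendered
  tables star p < 0.01 (`**`) and p < 0.05 (`*`).
- **Group comparisons**: Levene's test in the median-centred
  (Brown–Forsythe) variant — the robust common default, since the source
  names only "Levene's test" — one-way ANOVA, and Tukey HSD with the
  Tukey–Kramer correction for unequal n (scipy's `tukey_hsd`). With two
  groups the pooled-variance t-test is reported as well (F = t² holds to
  machine precision). The compact letter display uses the
  insert-and-absorb algorithm: groups not significantly different at the
  chosen level share at least one letter; the partition depends only on
  the significant-pair set, with letters ordered by group means.

The published correlation coefficients and p-values are **not**
reproducible: they depend on replicate-level data that were never
deposited. The package demonstrates the machinery on synthetic data only.

## Synthetic-data generator

The generator emulates the survey design: 4 species × 5 metals × 2 seasons
× 3 replicates (the study conditions; replicates configurable), drawn in
**dry weight** — the basis on which the instrument measures and censoring
limits are stated — from a log-normal law per cell. Log-normal because
concentrations are positive and right-skewed; the default coefficient of
variation is 0.15, a typical analytical-plus-biological spread for
triplicate tissue determinations, shared by all cells. A draw below the
metal's detection limit is emitted as a censored record carrying the
limit, exactly as an instrument would report it. Identical seeds give
byte-identical output (cells visited in sorted order, one RNG).

Cell means of the reproduction profile are anchored to published numbers:

- pooled wet-weight means back-solved from the published adult intakes via
  Cm = EDI·BW/(FIR·10⁻³);
- printed seasonal extremes where available (*W. attu* dry-season Cr 1.92,
  Pb 1.42, Cu 1.99, Cd 0.31; *C. mrigala* wet-season Cr 0.54, Cu 0.62
  mg/kg ww), with the other season solved from the pooled mean;
- unprinted season splits reconstructed by a dry:wet enrichment ratio of
  1.3 (dry-season concentrations run higher with low flow and
  evapotranspiration; the ratio preserves the pooled mean exactly and is
  labelled a reconstruction in the profile);
- fully censored cells (all As; *C. mrigala* wet-season Cd) given true
  means safely below the detection limit, so the pipeline's value is the
  deterministic LOD/2 substitution.

What passing tests show: the pipeline recovers the parameters of data that
satisfy its own assumptions (log-normal noise, independent cells, exact
design balance). Real tissue data add inter-fish correlation, size and age
covariates, season-dependent variance and possible non-detects near the
limit — none of which the generator emulates, so parameter recovery here
does not validate the substitution or pooling choices against real-world
violations.

## Numerical choices

- Internal arithmetic at full double precision; display rendering at 3
  significant figures with scientific notation below 0.01, matching
  survey-table conventions.
- Validation errors name the offending sample/row; a failed CLI run
  removes partial outputs.
- Pooled substituted_fraction is the fraction over replicates (not the
  mean of seasonal fractions), so it stays a provenance count.
- Test problem sizes: parameter recovery uses 10⁴ replicates per cell
  (sampling error ≈ 0.15/√10⁴ ≈ 0.15 % per cell, comfortably inside the
  1 % recovery tolerance); the Tukey permutation oracle uses 4·10³
  permutations with the comparison tolerance set from the Monte-Carlo
  error at that size.

## Known limitations

- LOD/2 substitution biases means for heavily censored cells; no
  maximum-likelihood or Kaplan–Meier censoring estimators are provided.
- The dry:wet season ratio for unprinted cells is a modelling choice, not
  data; seasonal statistics on synthetic data inherit it.
- Guideline limits ship as literature constants; exceedance output is only
  as good as the configured table.
- Single-toxicant additivity (HI) ignores interaction; no speciation
  (e.g. inorganic vs organic As) is modelled.
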