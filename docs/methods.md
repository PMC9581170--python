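# Methods

`heteroqtl` re-creates, end to end, the analysis used to dissect mid-parent
heterosis of grain traits in an elite *xian*/*indica* rice hybrid: a large F8
recombinant-inbred-line (RIL) panel from a biparental cross, testcrosses
(BC1F1) of every RIL back to the sterile seed parent, QTL scans run in
parallel on the RIL trait values, the testcross trait values and the
per-testcross mid-parent heterosis values, and a classification of each
detected locus's gene action. Because the underlying field data are not
deposited, the package ships a first-class simulator that reproduces the
study design, so every stage is testable without a download.

## Population simulator

**Meiosis.** Crossovers are placed without interference, so recombination
between two positions separated by *d* cM follows Haldane's map function,
r(d) = ½(1 − e^(−2d/100)). Each adjacent-marker interval recombines
independently with probability r.

**Single-seed descent.** Lines are selfed explicitly, one offspring per
generation, for a configurable number of meioses beyond the F1 (default 7,
i.e. an F8 panel). Residual heterozygosity therefore survives at the
expected rate (1/2)^7 ≈ 0.78% per locus, as in a real F8 panel, instead of
being forced to zero by an F∞ shortcut.

**Testcrossing.** Each BC1F1 genotype unites one RIL gamete with a pure
recurrent-parent gamete: loci where the RIL is homozygous transmit
deterministically; residual heterozygous loci transmit either allele with
probability ½. Phase between *adjacent* residual-het loci is not tracked —
at 0.78% heterozygosity the probability that two adjacent loci are both
heterozygous is ~6×10⁻⁵, so the simplification is negligible and the
testcross truth table (recurrent homozygote / heterozygote / missing) is
exact.

**Genotype coding.** 0 = recurrent-parent homozygote, 1 = heterozygote,
2 = donor homozygote, −9 = missing — matching the maintainer-line/donor
orientation of the emulated cross.

**Trait model.** A replicate measurement is
μ + Σᵢ(aᵢxᵢ + dᵢzᵢ) + Σⱼₖ aaⱼₖ xⱼxₖ + environment offset + N(0, σₑ),
with x ∈ {−1, 0, +1} counting donor minus recurrent alleles and z the
heterozygote indicator. a is the additive effect per donor-allele
substitution (trait units), d the heterozygote's deviation from the
mid-homozygote point, aa an additive-by-additive interaction. Environments
enter as additive offsets with an optional per-QTL multiplier; this is a
deliberate simplification — the real data show strong genotype-by-environment
interaction with no published model for it. `residual_sd_for_heritability`
inverts the generating model's variance decomposition
H² = V_g / (V_g + V_e/r) to hit a target line-mean heritability, which is how
the tests plant traits at the heritabilities printed for the study (0.99 for
grain shape down to 0.24 for yield).

**Fertility.** Testcross pollen fertility is two-regime: lines carrying at
least one donor (restorer) allele at the configured restorer locus draw
around a high mean (default 0.85), the rest around a low mean (default
0.30), clipped to [0, 1]. The real distribution among non-restorer
testcrosses is unpublished; these defaults simply keep the two regimes on
either side of the 0.70 decision boundary. Restorer lines are those with
fertility strictly above 0.70 ("more than 70%"); yield scans are restricted
to them, other traits use the whole panel.

**Determinism.** One run seed is mandatory; every stage draws from a
deterministically derived sub-stream (`SeedSequence([seed, crc32(stage)])`),
so reruns are byte-identical.

## Marker processing

Markers are dropped when minor-allele frequency (heterozygotes counting
half) falls below 0.01, missingness exceeds 0.2, or the heterozygote
fraction exceeds 0.1. The heterozygote filter mirrors the study's removal of
loci "with a high frequency of the heterozygote"; its threshold is not
published, so 0.1 is an explicit assumption exposed as a parameter.

Adjacent markers whose genotype columns agree on every co-observed line
collapse into a bin; at least 30 co-observed lines are required before two
columns are declared redundant (the exact redundancy rule of the original
binning software is unstated). Each bin is represented by the member with
the lowest missing rate, ties broken by lowest physical position — a
deterministic stand-in for the original "random gene when the missing rates
were equal". Physical coordinates are 1-based closed intervals; genetic
positions are per-chromosome with origin 0. Per line, collapsing loses no
crossover interval, which the tests verify by run-length-encoding genotype
rows before and after binning.

Testcross genotypes are deduced from the parental RIL exactly as in the
study: RIL homozygous like the recurrent parent → recurrent homozygote; the
opposite homozygote → heterozygote; heterozygous or missing RIL call →
missing.

Map re-estimation converts adjacent-bin discordance R (on co-observed
homozygous calls) to a meiotic recombination fraction via the
inbred-by-selfing relation r = R/(2(1−R)) and then to distance with
Haldane's function. The relation is the F∞ limit; at F8 it carries a ≤1%
bias which is documented rather than modelled. R ≥ 0.5 raises an error
naming the offending pair.

## QTL scans

The 1-D scan follows the two-step inclusive-composite-interval-mapping
scheme:

1. **Cofactor selection** — forward–backward stepwise linear regression on
   the bin scores (RIL: −1/0/+1; testcross: 0/1; missing mean-imputed).
   Entry requires partial-F p ≤ PIN (default 0.001), removal p > POUT
   (default 2×PIN; only PIN is published, and 2×PIN is the conventional
   default of this software family). Ties resolve to the lowest physical
   position, making selection deterministic.
2. **Interval scan** — at every grid position (1 cM step plus every bin
   position) each line's two QTL-class probabilities are computed from its
   flanking bins through a Markov approximation with inbred-panel
   discordance ρ(d) = 2r(d)/(1+2r(d)) as the transition probability;
   uninformative flanks fall back to the 0.5/0.5 design prior. A
   two-component normal mixture with equal class variances (a stability
   choice; the original is silent) is maximized by EM (tolerance 10⁻⁶, at
   most 200 iterations) on the cofactor-adjusted phenotype; cofactors inside
   or flanking the scanned interval are left unadjusted. LOD is the base-10
   log likelihood ratio against a single normal; PVE = 100·(1 − σ̂²/σ̂₀²).
   At a fully informative bin the mixture collapses to exact two-class
   regression, which is the oracle identity the acceptance suite checks to
   10⁻⁶.

The same machinery scans all three datasets. RIL scans estimate the additive
effect a (half the homozygote contrast). Testcross scans estimate a+d
(heterozygote vs recurrent homozygote). Heterosis scans attach the
per-testcross mid-parent heterosis percent, H_MP = 100(F1 − MP)/MP, to the
testcross genotypes, so their effect estimates dominance, in percent units.
Deduced testcross genotypes inherit the RIL panel's linkage structure, which
is why the inbred-panel transition probabilities are reused for them.

**Thresholds.** The default LOD thresholds are 3.0 (1-D) and 5.0 (2-D), the
values the study fixed from 1,000 permutations at 95% confidence.
`permutation_threshold` recomputes a genome-wide threshold as the
(1−α) quantile of the maximum LOD over seeded phenotype permutations, with
cofactors reselected per permutation; it is applied globally (whether the
original thresholds were per-trait is unstated, and global is the default
here).

**Peak calling.** Local maxima at or above threshold are reported; peaks
closer than 10 cM merge into the higher one; the support interval is the
1.5-LOD drop clipped to the chromosome, with physical bounds taken from the
flanking bins.

**2-D scan.** On a 5 cM grid (PIN 0.0001 for its cofactors) every
admissible position pair — all inter-chromosomal pairs, intra-chromosomal
pairs at least 20 cM apart to avoid linkage artifacts — is tested by
comparing [1, x₁, x₂, x₁x₂] against [1, x₁, x₂] on adjusted phenotypes,
where xᵢ are expected donor-dose scores. This regression formulation is a
deliberate simplification of the full four-class mixture: with expected
scores it targets the same additive-by-additive contrast at a fraction of
the cost. Pairs with interaction LOD ≥ 5.0 are filtered to 2-D local maxima
(one grid step in either locus), so one interaction reports one pair;
degenerate pairs (interaction collinear with the main effects) are skipped.

## Phenotype statistics

Broad-sense heritability comes from a one-way ANOVA across lines:
σ²_g = (MS_line − MS_error)/r truncated at zero (the standard estimator
pathology; the original is silent), H² = σ²_g/(σ²_g + σ²_e/r) on a line-mean
basis. Correlations are Pearson on line means, within environment or on the
same-trait between-environment diagonal. The F1-vs-mid-parent contrast is a
two-sided two-sample t-test. The sterile seed parent never grows in the
field; its trait values are those of its fertile near-isogenic maintainer,
supplied through configuration. Environments are never pooled.

## Gene-action classification

Calls of the same trait and environment whose support intervals overlap or
whose peaks lie within 5 cM (transitive closure; the chaining risk is
accepted and documented) form one cluster with up to three effect estimates:
â (RIL), (a+d)̂ (testcross), and the heterosis-scan effect.

* Detected in only one of RIL/testcross → **additive (A)**.
* Otherwise dominance evidence exists. When both â and (a+d)̂ are available,
  d̂ = (a+d)̂ − â on the trait scale and the dominance ratio
  ρ = |2d̂/(â+d̂)| decides: ρ < 1 → **incomplete dominant (ID)**, ρ > 1 →
  **overdominant (OD)**; the ρ = 1 tie falls to ID (conservative toward
  partial dominance).
* Detected only in the heterosis dataset → OD.
* When the heterosis scan is the sole source of d alongside exactly one
  trait-scale estimate, ρ would mix percent and trait units; such clusters
  are classified OD and the heterosis effect is used for sign and detection
  only.
* Any dominance-showing cluster whose d̂ opposes the trait-increasing
  allele (oriented d̂ < 0, orientation from the sign of â, else (a+d)̂) is
  **underdominant (UD)**, overriding ID/OD. "Negative" dominance is
  interpreted relative to the favorable-allele direction; this orientation
  convention is an explicit assumption.

The rule set is an exhaustive partition (property-tested over randomized
effects and detection patterns). One consequence worth knowing: a truly
additive locus detected in both the RIL and testcross scans is rated by the
ratio rule (ρ ≈ 0 → ID, or UD when the noise-level d̂ happens to be
negative), exactly as the published rules dictate — additive loci are
labelled A only when one of the two trait scans misses them.

Cross-environment comparison reuses the matching rule to label clusters
common or environment-specific. Multi-trait regions merge physically
overlapping support intervals spanning ≥ 2 traits; each region is flagged
`same` or `opposite` according to whether the favorable-allele directions
(sign of the donor effect times a per-trait larger-is-favorable orientation
map) agree. Epistasis overlap between two scans matches pairs order-free
within one grid step per locus and reports 100·|common|/|union| — the union
denominator is a documented choice, as the original denominator is unstated.

## Problem sizes used in the tests

The acceptance suite runs at desk scale: genotype oracles at 10,000 lines,
scan-oracle equivalence and permutation calibration on a 300-line, 200-bin
panel (200 permutations, 200 null traits), and parameter recovery over 50
replicates of 1,000 lines with five planted loci (one per chromosome,
d/a ∈ {0, 0.3, 0.3, 1.5, −1.5}, each with PVE ≥ 8% in at least one dataset).
The headline counts of the original study (114 main-effect QTL, 359
epistatic pairs, 855 bins) depend on its unreleased field measurements and
are not reproducible from printed numbers; what is checked instead is every
quantity that *is* recomputable plus the statistical behaviour of each
component under the study design.

## Known limitations

* No selection, mutation, segregation distortion, or cytoplasmic
  male-sterility mechanism beyond the single restorer locus; simulated
  panels are cleaner than the real one (no genotyping error model).
* The Markov flanking-bin approximation and the F∞ inbred correction at F8
  are standard but approximate; both biases are far below the mapping
  resolution at the simulated densities.
* The 2-D scan tests only additive-by-additive interactions, as in the
  original; additive-by-dominance and dominance-by-dominance terms are out
  of scope, as is multi-environment joint mapping.
* Passing recovery tests on simulated data shows the machinery is correct
  under the generating model, not that real-data QTL counts would be
  reproduced.
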