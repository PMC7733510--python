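# Methods

## Study model

The package assumes a transplantation study with this shape: one or more
human donors, each contributing a pooled fecal inoculum sequenced as 3–4
aliquots; per donor, one or two recipient arms of germ-free animals
(typically 3–10 animals each); fecal samples per animal on a fixed
schedule of days post-inoculation (default 2, 7, 14, 21, 28, 35, 40).
All inference starts from a quality-filtered integer ASV count table and
per-sample design metadata. Raw-read processing (denoising, chimera and
contaminant removal, taxonomy assignment) is out of scope; taxonomy and
a phylogeny are consumed, never produced.

All containers are identifier-keyed: row/column order in input files
never affects any result. Counts must be integers; fractional input is
rejected rather than rounded because detection calls and count-based
testing assume read counts.

## Thresholds and their defaults (`StudyDesign`)

| parameter | default | meaning |
|---|---|---|
| `min_sample_depth` | 10,500 reads | samples with *fewer* reads are removed; the comparison is strict, so a sample at exactly 10,500 survives |
| `detection_min_count` | 1 read | presence = count ≥ this; membership in the donor core and all detection calls use it |
| `persistence_fraction` | 0.5 | a day qualifies only when the detection fraction strictly exceeds it (2/4 animals does not qualify; 2/3 does) |
| `persistence_min_timepoints` | 4 (of 7) | days needed for persistence, and non-significant days needed for a donor-like call |
| `alpha` | 0.05 | significance level for per-day differential calls |

The depth filter is applied to the input table as given (i.e. after
whatever upstream taxon filtering produced it); the order is documented
here because it is not derivable from the table itself.

## Colonization ladder

Per donor × host group, every core ASV receives exactly one status:

- `non_colonizer` — never detected in any of the group's fecal samples;
- `colonizer` — detected in ≥ 1 fecal sample (one read in one animal on
  one day suffices, by design);
- `persistent_colonizer` — for each scheduled day, detection fraction =
  (animals with a detection that day) / (animals with a sample that
  day); the ASV is persistent when the fraction strictly exceeds
  `persistence_fraction` on at least `persistence_min_timepoints` days.

The per-day denominator counts animals that actually contributed a
sample, so deaths and missed collections shrink the denominator rather
than counting as non-detections. An enrolled-animal denominator is
available (`denominator="enrolled"`) for sensitivity analysis. A
scheduled day with no samples contributes nothing; since the threshold
stays "≥ 4 of 7", missingness can only make the rule more conservative.

Percentages in summaries are rounded half away from zero (1 decimal for
table-style output, 0 decimals for prose-style output) with the core
size as denominator throughout.

## Donor-like abundance maintenance

For each persistent colonizer, the animals' counts on each scheduled day
are compared against the donor's inoculum aliquots:

1. **Normalization.** Median-of-ratios size factors are fitted jointly
   on the day's animal samples plus the aliquots, over all ASVs: the
   reference is the per-ASV geometric mean across samples, restricted to
   ASVs positive in every sample, and each sample's factor is the median
   of count/reference. When no ASV is positive everywhere the factors
   are recomputed on counts + 1 (a configuration fallback, reported as
   such).
2. **Test.** A two-group negative-binomial Wald test: per-ASV dispersion
   by pooled method of moments, `α̂ = max((s²_pool − μ̄)/μ̄², 1e-8)`;
   Wald statistic `(log μ̂_A − log μ̂_D) / SE` with
   `SE² = (1/μ̂_A + α̂)/n_A + (1/μ̂_D + α̂)/n_D`. The statistic is
   referred to a **Student t with n_A + n_D − 2 degrees of freedom**
   rather than a normal: with group sizes of 3–10 and a plug-in
   dispersion, the normal reference is anti-conservative (≈ 0.09 type I
   at nominal 0.05 for two groups of 5), while the t reference measures
   0.045–0.049 in null simulation. This is a deliberately small core of
   the DESeq2-style procedure — no dispersion shrinkage toward a trend,
   no outlier (Cook's distance) filtering, no independent filtering —
   and every output row carries its `test_mode` label. A nonparametric
   fallback (`rank_sum`) tests per-sample relative abundances instead,
   exact for small tie-free groups.
3. **Multiplicity.** Benjamini–Hochberg step-up across the ASVs tested
   within one (donor, host, day) family — the natural reading of testing
   "at each sampling time point". A `global` scope (one family across
   all days) is available and changes results; the choice is a
   configuration constant covered by a regression test.
4. **Aggregation.** A day is non-significant when adjusted p ≥ α. An ASV
   "maintained a donor-like abundance" when non-significant on at least
   `persistence_min_timepoints` days — the same threshold object as
   persistence. Untested days (too few samples) count as neither.

Fold changes are reported as log2 of the ratio of normalized group means
with a 0.5 pseudocount; the pseudocount is for reporting only and never
enters a test. Zero group means in the Wald statistic are floored at
half a normalized count spread over the group — a numerical guard, not a
pseudocount. Group means of all-zero ASVs in both groups are reported as
p = 1, log2FC = 0 by convention. Each animal's sample on a day is one
observation; cage or litter structure is not modeled.

## Diversity support

- **Shannon index**, natural log (base configurable), computed on all
  ASVs — rare taxa matter for alpha diversity, so the core restriction
  is not applied here.
- **Bray–Curtis** on per-sample relative abundances (raw-count mode
  available); **unweighted UniFrac** on presence/absence against a
  rooted tree (tips missing from the tree raise, or are dropped with a
  warning behind a flag). Matrices are computed with scikit-bio and
  validated for symmetry, zero diagonal and finiteness.
- **PCoA** is classical scaling: double-center −D²/2, eigendecompose,
  keep positive eigenvalues; negative eigenvalues (non-Euclidean input)
  are *dropped and counted*, not corrected — the count is part of the
  result so non-Euclidean inputs are visible.
- **Distance to donor**: per fecal sample, the mean of its distances to
  its donor's aliquots (one observation per sample); an all-pairs mode
  keeps each (sample, aliquot) distance as its own observation.
- Beta-diversity questions about engraftment are asked of the
  core-restricted table by default (configurable), alpha diversity of
  the full table.
- No rarefaction: depth is handled by relative abundance (Bray–Curtis)
  or presence (UniFrac).

## Synthetic-data generator

The simulator emulates the statistical structure the classifier assumes,
with defaults shaped like the study design above (four donors of 30–150
ASVs, 3–4 aliquots, a 7–10-animal mouse arm and a 3–4-animal piglet arm,
depths in the mid-tens of thousands, one piglet of the first donor lost
after the day-2 collection):

1. A fixed ASV pool (default 400) with phyla drawn from a mixture
   (Firmicutes 0.60, Bacteroidetes 0.22, Actinobacteriota 0.08,
   Proteobacteria 0.06, Verrucomicrobiota 0.02, Desulfobacterota 0.02)
   and synthetic nested family/genus labels. Donors sample their ASVs
   from the pool, so identifiers are comparable across donors.
2. Donor abundances: normalized exp(Normal(μ, σ)) draws (default
   σ = 1.5, spanning ≥ 2 orders of magnitude), sequenced as independent
   multinomial aliquots.
3. Colonization: per animal × ASV, Bernoulli with a phylum-specific
   probability (defaults: Firmicutes 0.35 in mice vs 0.70 in piglets;
   Bacteroidetes 0.85 in both — the headline host contrast). Colonized
   ASVs get the donor abundance × LogNormal(0, σ_mod) (default 1.0),
   renormalized within the animal.
4. Dynamics: each carried ASV goes extinct with probability 0.02 per
   time point, absorbing (no recolonization) — the simplest mechanism
   that can break the ≥ 4-of-7 rule. Deaths are modeled as missing
   (animal, day) samples.
5. Reads: multinomial(fecal depth) over the surviving community; animals
   carrying nothing yield zero-count samples for the depth filter to
   remove.

Ground truth records colonization and per-day carriage flags, plus
labels computed on carriage with the same majority/≥ 4-day rule as the
classifier. All randomness flows from the single config seed.

**What the simulator does not capture** — and hence what passing tests do
not show about real data: species interactions and resource competition,
recolonization, cage effects and coprophagy, variable per-sample depths,
compositional sequencing artifacts, taxonomy errors, and per-animal
colonization correlation. The last point matters when interpreting
group-level colonizer percentages: under independent per-animal
Bernoulli draws, the probability that *some* animal is colonized
saturates as 1 − (1−p)^n, so arms with many animals approach 100 %
colonizers even for host-disfavoured taxa, whereas real studies show
much lower group-level percentages. Persistence (a majority rule) does
discriminate, which is why simulation-based checks of host preference
use equal-sized arms and why the per-donor summary percentages of a real
study are not a target of the simulation.

## Numerical and design choices

- Presence is literal nonzero detection (≥ 1 read) because the study
  design never states a minimum count; it is configurable for
  sensitivity analyses, and raising it can only shrink cores
  (anti-monotone, property-tested).
- Strict ">50 %" and strict "< 10,500" follow the design's wording
  exactly; both boundaries are locked by tests.
- Two summary-table conventions in the source material are internally
  inconsistent (cells that match neither rounding convention, and one
  row whose persistence percentage uses colonizers rather than core as
  denominator); the package always uses half-away-from-zero rounding
  with the core as denominator and does not chase those cells.
- Cross-host contingency supports `basis=persistent_colonizer` in
  addition to the colonizer basis — the partition logic is identical.
- PCoA corrections (Cailliez/Lingoes), weighted UniFrac, PERMANOVA,
  compositional (CLR-type) methods, zero-inflation and longitudinal
  mixed models are out of scope; the procedure is per-day
  cross-sectional by design.

## Problem sizes used in the checks

The test and acceptance suites run the pipeline on simulations with 4
donors × 2 hosts (≈ 360 samples × 120–285 ASVs), validate the persistence
rule against a brute-force transcription on hundreds of random presence
tensors (≤ 4 animals × 7 days × 6 ASVs) plus the complete single-animal
enumeration, check host-preference recovery over 100 seeded replicates
(80-ASV donor, 5-animal arms), and calibrate the Wald test on 1000 null
negative-binomial replicates. These sizes were chosen to make each check
statistically meaningful at interactive runtimes; all are seeded and
deterministic.

## Known limitations

- The NB test is a simplified two-group Wald procedure; for tiny groups
  with strong outliers the rank-sum mode is the safer choice.
- Unweighted UniFrac requires every table ASV to be a tree tip; the
  drop-with-warning flag changes the community definition and should be
  used knowingly.
- The colonizer rung is maximally sensitive by definition (one read in
  one sample); cross-study comparison of colonizer percentages is
  confounded by group size, as discussed above.
- ASV identifiers are assumed comparable across donors (same denoising
  universe) wherever unions or shared cores are computed.
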