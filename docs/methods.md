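# Methods

`varprio` implements the variant-interpretation workflow used in germline
hereditary breast/ovarian cancer (HBOC) cohort studies, specialized to
BRCA2 but configurable for any protein. This note documents the models and
procedures, the parameters that matter, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations and documented divergences.

## Nomenclature parsing

Variant catalogues describe each change twice: as a coding-DNA edit
(`c.3264dup`) and as its protein consequence (`p.Gln1089fs`). The parser
supports the subset of HGVS that occurs in germline panel reports:

- protein level: `p.<ref3><pos><alt3>` (missense), `p.<ref3><pos>Ter`
  (stop-gained), `p.<ref3><pos>fs` or `p.<ref3><pos><ins3>fs` (frameshift;
  the inserted residue before `fs` is normalised away, so `p.Val3079fs`
  and `p.Val3079Phefs` denote the same change);
- cDNA level: substitution (`N>M`), `dup`, `del`, `delins`, with single
  positions or closed ranges `a_b`.

Positions are 1-based on the canonical protein (UniProt P51587, 3418
residues for BRCA2) and are trusted as printed: no transcript-level
validation (does c.3264 fall in codon 1089?) is performed, and no attempt
is made to reconcile transcript-version differences between records. A
variant whose cDNA edit is a delins but whose protein consequence is a
single substitution (e.g. `c.6415_6416delinsAT` → p.Glu2139Leu) is
classified missense: the protein-level consequence drives everything
downstream, and the cDNA edit kind is retained as metadata only.

Records join across tables on a stable key: the rsID when one exists,
otherwise the cDNA string. In the packaged catalogue one variant
(`c.9812T>C`) lacks an rsID.

## Domain localization

Functional domains are closed, 1-based residue intervals loaded from JSON.
The packaged BRCA2 annotation has four intervals:

| domain             | interval  | critical |
|--------------------|-----------|----------|
| BRC repeats        | 1003–2082 | yes      |
| DNA-binding domain | 2804–3054 | yes      |
| terminal DBD       | 3052–3185 | yes      |
| C-terminal region  | 3190–3418 | no       |

`map_position` is total and deterministic: *inside* if any interval
contains the position (ties between overlapping intervals broken by
smallest span, then input order — so the DBD/terminal-DBD overlap at
3052–3054 resolves to the terminal DBD); *boundary* if the position lies
in an annotation gap within `boundary_window` residues (default 5) of some
interval edge; *outside* otherwise. The boundary category exists because
annotation edges are themselves uncertain: residue 3187 falls in the
4-residue gap between the terminal DBD and the C-terminal region and is
best described as boundary rather than forced into either neighbour.

Design choices made here:

- The terminal DBD is flagged critical alongside the BRC repeats and the
  DBD proper: variants in the C-terminal portion of the DBD disrupt the
  same DNA/DSS1-binding function, and the packaged catalogue's
  terminal-DBD missense variants behave as escalated in the published
  triage.
- The C-terminal region (3190–3418) is configured non-critical: it is a
  heterogeneous region (phosphorylation sites, NLS, RAD51 interaction)
  without the focal structural role of the DBD, and boundary/inside calls
  against it do not escalate triage.
- Boundary localization never escalates (see rubric below).

## Predictor-score integration

SIFT and PolyPhen-2 scores are produced by external annotation (Ensembl
VEP) and supplied as data; only missense variants have scores, and some
missense variants are absent from the annotators entirely. Calls are
derived by thresholding: SIFT ≤ 0.05 → deleterious, PolyPhen-2 ≥ 0.85 →
damaging (both cutoffs inclusive and overridable via `ThresholdConfig` or
the `--sift-cutoff`/`--polyphen-cutoff` CLI flags). The 0.85 PolyPhen
cutoff is the analysis's choice, not the tool's canonical category
boundaries — PolyPhen's own "possibly damaging" band straddles it. The
printed categorical labels are therefore carried as display metadata only;
the rubric consumes the threshold calls exclusively. Missing scores yield
`unknown` calls that contribute no evidence in either direction.

## Physicochemical substitution analysis

For a missense change ref→alt the report compares fixed per-residue
scales: Zamyatnin (1972) mean residue volumes for size, the Kyte–Doolittle
(1982) hydropathy index for hydrophobicity, and net side-chain charge at
physiological pH (Asp/Glu negative; Lys/Arg positive; all others,
including His, neutral). Comparisons are strict; equal values report
"similar". Flags mark proline introduction (backbone rigidity, helix
disruption), glycine introduction (flexibility), and charge loss/gain.
The report is antisymmetric by construction: reversing a substitution
flips the size and hydrophobicity arrows and reverses the charge
transition.

Two cells of the published seven-row property table do not reproduce from
any standard scale, and the implementation reports the scale-derived
values rather than matching the printed cells:

- p.Asn3187Ser is printed as "Negative → Neutral", but asparagine carries
  no side-chain charge at physiological pH; the report says
  neutral → neutral.
- p.Glu2139Leu is printed as "↓ Size", but leucine (166.7 Å³) exceeds
  glutamate (138.4 Å³) on the Zamyatnin scale (and on Tsai/Chothia
  volumes); the report says ↑ Size. The charge loss and hydrophobicity
  gain in the same cell do reproduce.

The other five rows reproduce fully. The property module emits no
damaging/benign verdict: automated structural-report tools also weigh
evolutionary conservation, which is out of scope here, and property
reports support interpretation without moving the triage level.

## The triage rubric

The core procedure assigns each variant an ordered priority level
(Low < Moderate < High) for follow-up — explicitly not an ACMG/AMP
pathogenicity classification. Starting from rank 0:

1. **Truncating rule.** Frameshift and stop-gained variants are High
   outright; no other evidence is consulted.
2. **Domain escalation.** Missense inside a critical domain: +1.
   Boundary and non-critical-domain localization add nothing.
3. **Predictor escalation.** Concordant adverse calls (SIFT deleterious
   AND PolyPhen damaging): +1. Exactly one adverse call: also +1, but the
   final level is capped at Moderate. The single-predictor increment
   (before the cap) is required for outside-domain, single-predictor
   variants to reach Moderate rather than Low, which is how the published
   triage behaves.
4. **ClinVar escalation.** Any Pathogenic or Likely-pathogenic assertion
   in the aggregate label set: +1. Labels inside "conflicting
   classifications" aggregates count — a conflicting VUS/Likely-pathogenic
   entry carries the escalation. Matching is by exact normalized label
   ("pathogenic", "likely pathogenic", "probably pathogenic"),
   case-insensitive, never by substring.
5. The single-predictor cap is applied (rank := min(rank, 1)), then the
   rank is clamped to High.

Every decision is written to a six-entry ledger (`truncating_rule`,
`domain_escalation`, `predictor_escalation`, `single_predictor_cap`,
`clinvar_escalation`, `high_cap`), and `level_from_ledger` recomputes the
level from the trace alone; the test suite audits this equality over the
packaged catalogue and 1,000 random evidence combinations. The rubric is
monotone: adding adverse evidence never lowers a level, removing ClinVar
support never raises one.

On the packaged 13-variant catalogue the rubric yields 7 High (six
truncating plus the concordantly-predicted terminal-DBD missense
p.Ala3122Pro), 4 Moderate and 2 Low, row-for-row identical to the
published suggested priority levels.

## Exact-test frequency comparison

Per-variant cohort carrier counts (k out of 140 patients) are compared
with reference counts — other cohorts' carriers, or gnomAD/dbSNP allele
counts out of allele numbers — by the two-sided Fisher exact test.
Conditional on the margins, the p-value sums the hypergeometric point
probabilities of every 2×2 table whose probability does not exceed the
observed table's, with a 1e-7 relative tolerance absorbing floating-point
ties. Point probabilities are computed in log space (`gammaln`), summed by
log-sum-exp, and clamped to (0, 1], so million-scale database denominators
are handled without overflow. The implementation agrees with exact
integer-arithmetic enumeration to < 1e-12 over every table with total
count ≤ 60 (631,595 tables), and with `scipy.stats.fisher_exact` on the
packaged comparisons; a null-calibration simulation (n₁=140, n₂=10,000,
p=0.02, 10,000 replicates) confirms the test is conservative at α=0.05
(observed rejection rate ≈ 0.03).

Two deliberate fidelity choices:

- **Unit mismatch preserved.** Cohort counts are carriers-per-patient
  while database counts are alleles-per-allele-number. The comparison
  mirrors how published frequency tables are constructed; the report's
  `kind` column labels each row so the mismatch is visible.
- **No multiple-testing correction** is applied, matching the source
  analysis; the 21 packaged comparisons are reported raw.

Display format: p-values at 4 decimals, with values below 0.00005 shown
as `<0.0001`.

Documented divergences: the published cell "0.00046 (Mexico)" for the
2/140 vs 1/3842 comparison is not what any exact-test construction of
those counts yields (enumeration gives ≈ 0.0036); it is excluded from
reproduction checks. The published 0.079 for 3/140 vs 1/387 similarly
computes to 0.059. The five other spot-checked published p-values (0.0036,
0.0019, 0.0007, 0.0249, 0.024) reproduce at printed rounding.

## Cohort statistics

Descriptive summaries report counts/percentages (rounded half-up to whole
percent, as stratified clinical tables print them), mean ± SD and range
per diagnosis group; a single-patient group reports SD 0 with an
`sd_undefined` flag. Carrier vs non-carrier comparisons use the same
Fisher implementation as the frequency module (single code path) for
categorical variables and Welch's unequal-variance t-test for continuous
ones — the source analysis names no tests, and Welch is the conventional
default when variances are not assumed equal.

Reproduction status for the published stratified table, from its printed
counts: all five proportion pairs (29/6, 100/57, 36/69, 75/13, 0/80)
reproduce exactly; the overweight (p=0.019) and bilaterality (p=0.037)
p-values reproduce at printed rounding; chemotherapy response reproduces
to two decimals (printed 0.032, computed 0.0331); the family-history
(printed 0.004, computed 0.00088) and abortion-history (printed 0.018,
computed 0.0090) p-values do not reproduce from their printed counts under
any standard two-sided exact construction and are treated as documented
divergences. The published age comparison is itself printed inconsistently
in the source (p=0.028 in the text, p=0.003 in a table footnote) and is
not used as a reproduction target. One published table labels the OC
0%-vs-80% row "menopause status" where the accompanying text calls it
"abortion history"; variable labels are treated as data and not
adjudicated.

## Synthetic-data generator

The patient-level data behind published cohort tables is not deposited, so
the generator produces stand-in cohorts with the statistical structure the
analysis assumes. Defaults encode the study conditions: 116 BC / 19 OC /
5 dual-diagnosis patients; carrier prevalence 14/116, 4/19, 0/5; age
means ± SD 46.9 ± 13.3, 56.6 ± 11.1, 49.0 ± 10.7 years, truncated to
[18, 95] (the lower bound is the cohort's inclusion criterion; truncation
raises the realized BC mean by ≈ 0.5 years, within the 2% recovery band);
menarche ages truncated to [8, 16]; categorical probabilities back-solved
from the published marginal and stratified counts. Four covariates are
carrier-associated, with per-stratum probabilities taken from the
published carrier/non-carrier columns: overweight (29% vs 6% in BC),
first-degree family history (100% vs 57% in BC), complete chemotherapy
response (36% vs 69% in BC), bilaterality (75% vs 13% in OC), plus
abortion history in OC (0% vs 80%). All other covariates are drawn from
group marginals identically in both strata. Covariates are sampled
independently of one another given the carrier stratum — published tables
report only marginal stratified counts, so no cross-covariate dependence
is identifiable.

Two allocation modes:

- **quota** (default): within each (group, stratum), level counts are
  fixed by largest-remainder rounding of n·p and assigned in shuffled
  order. Generated cohorts reproduce the published stratified margins
  exactly up to integer rounding, which is what makes parameter recovery
  a meaningful check — at 50,000 patients, prevalence, age means and the
  stratified covariate odds ratios are recovered within 2% relative
  error, with the residual error coming from rounding and age truncation
  rather than sampling noise.
- **bernoulli**: every patient drawn i.i.d.; margins then fluctuate with
  binomial sampling variance. Use this mode to emulate genuine sampling
  variation, e.g. for power or calibration experiments.

The panel generator emits variant catalogues whose every record
round-trips through the package's own parsers, with a configurable
consequence mix (default 7:5:1 missense:frameshift:stop-gained, the
packaged catalogue's proportions), positions sampled without replacement
over 1..3418, SIFT/PolyPhen scores drawn from adverse (U(0, 0.05),
U(0.85, 1)) or benign (U(0.06, 1), U(0, 0.84)) components independently
per predictor with configurable adverse weight, and ClinVar label
frequencies weighted toward uncertain significance as rare-variant
catalogues are. Truncating and a configurable fraction of missense
variants carry no scores.

What the generator does **not** emulate: real allele-frequency spectra or
linkage structure, sequence-level errors, correlated comorbidities,
informative missingness, or recruitment bias. Tests passing on synthetic
cohorts therefore demonstrate that the statistical machinery is correct
under the stated model, not that the model captures every feature of real
HBOC cohorts.

All randomness flows through a single `numpy` generator seeded from the
spec; identical spec + seed gives byte-identical output files. Seeds are
mandatory in the CLI (no wall-clock seeding).

## Numerical and formatting choices

- Fisher tie tolerance 1e-7 relative (absorbs float ties in the
  point-probability comparison); p clamped to (0, 1].
- Odds ratio (k₁(n₂−k₂))/((n₁−k₁)k₂), with division by zero reported as
  infinity (NaN for 0/0).
- Percentages: 2 decimals in frequency reports, half-up integers in
  stratified cohort displays; p-values 4 decimals. Fixed formatting and
  stable sorts make pipeline re-runs byte-identical.
- Priority report ordering: High → Low, then ascending protein position.
- Problem sizes used by the packaged checks: the 13-variant catalogue and
  140-patient cohort throughout; 50,000 patients for parameter recovery;
  10,000 replicates for null calibration; exhaustive enumeration to total
  60 for the exact-test oracle; 1,000 random evidence combinations for
  rubric properties.

## Known limitations

- The HGVS subset excludes intronic, UTR, inversion and mosaic notation;
  there is no VCF ingestion or genome-build liftover.
- Domain annotation is interval-based; no secondary-structure or 3-D
  proximity reasoning.
- The rubric's levels are research-prioritization heuristics; they are
  not calibrated probabilities of pathogenicity and must not be read as
  clinical classifications.
- Conservation-based evidence (a component of structural-report tools) is
  out of scope; the property module is physicochemical only.
- The carrier-vs-database comparison inherits the carriers-vs-alleles
  unit mismatch discussed above; treat those p-values as descriptive
  flags, not as effect estimates.
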