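# Methods

## Data model and preparation

Records are drug × species × SOC/PT observations; phase is fully
determined by species (human ⇒ clinical, panel species ⇒ preclinical).
MedDRA terms are opaque labels; the only hierarchy constraint enforced
is that a PT maps to exactly one SOC within a dataset, because the
Bonferroni families are defined per SOC — a PT under two SOCs is a hard
load-time error rather than a silent pick. Species strings are
normalized through an editable alias table shipped as package data
(`data/species_aliases.csv`); rows whose species cannot be mapped are
returned in a per-row rejection report, never silently dropped.

Preparation applies, in order: exclusion of post-marketing and refuted
records (a record carrying both flags is counted under both reasons,
with the overlap reported separately); deduplication on
(drug, species, PT) keeping the first instance in input order (phase is
implied by species and SOC by PT, so the triple identifies one
observation); and restriction to dual-reported drugs (≥1 preclinical
and ≥1 clinical record), which defines the analysis universe used for
true-negative estimation. Filtering and deduplication commute whenever
duplicate records of a key agree on their flags — which holds when the
flags are properties of the drug–AE association, as here — and all
three steps are idempotent.

Cross-source drug identity is resolved by a strict cascade
(name → synonym → PubChem CID → CAS → SMILES); the first level with any
hit wins and is recorded. Name and synonym comparison is
case-insensitive after trimming; SMILES comparison is exact-string (a
normalizer can be plugged in upstream). A matched entity adopts the
canonical (left-source) id; an unmatched one keeps its own. When
several canonical candidates tie at the winning tier, the
lexicographically smallest id is chosen and a warning logged — the
sources give no basis for reconciling conflicting identifiers across
tiers, so no cross-tier arbitration is attempted.

## Contingency tables and universes

For a stratum, the universe N is the set of dual-reported drugs that
(a) fall in the modality slice — drugs with unknown modality stay in
the "all" aggregate but are excluded from SM/Bio slices, preserving the
aggregate without asserting a label — and (b) have ≥1 preclinical
record under the stratum's species rule and ≥1 clinical record, after
the exposure restriction when the stratum is exposure-controlled. Under
the all-species rule an AE is preclinical-present if observed in any
panel species. Every universe drug is classified exactly once, so
TP+FP+FN+TN = N always; TN is an estimate by construction (absence of a
report is not a measured negative). This is the most literal universe
consistent with the dual-reporting restriction; since curated databases
never state their universe, it is an explicit dialect switch of this
implementation, logged per stratum, and no numerical agreement with any
specific external analysis is claimed.

## Exact test and correction

The two-tailed Fisher exact p uses the point-probability convention:
the sum over all tables with the observed margins whose hypergeometric
point probability is at most that of the observed table. Because all
point probabilities share the denominator C(N, r1), the "at most as
probable" comparison is performed on exact integer numerators
C(c1, k)·C(c2, r1−k) (computed by an exact integer recurrence), so tie
decisions never depend on floating-point rounding; the final p is one
big-integer division. A zero margin yields p = 1 by convention and is
logged. Bonferroni families are (SOC, stratum, mode ∈ {identical,
cross-term}) and include every test actually performed, significant or
not; p_adj = min(1, m·p_raw), significant iff p_adj < 0.05 (α
configurable).

Metric conventions: LR+ = +∞ when FP = 0 and TP > 0 (+∞ serializes as
the literal `Inf`, compares above any finite value, and ties at the top
in rank-based procedures); a metric whose denominator has no
observations is NaN and listed as undefined, never coerced to 0.
Results with TP below a configurable threshold (default 5) carry a
`low_tp_flag`, since small-TP and infinite-LR estimates are unstable.

## Cross-term analysis and semantics

Cross-term pairs are the full preclinical × clinical PT cross product
within each SOC (never across SOCs). Identical pairs are enumerated in
this mode too — the correction family must equal the set of tests
performed — but flagged. "Additional unique endpoints" are counted over
significant non-identical pairs after removing terms already
significant in identical-term mode, by inclusion–exclusion
(n_total = n_clin + n_preclin − n_shared).

Embeddings come from a provider contract (term → unit vector,
deterministic per provider version). The default provider hashes
character 3-grams into a 64-dimensional vector with a keyed sha256 —
fully reproducible offline and across platforms, lexical-overlap-only,
and intended for plumbing and tests; a live semantic-embedding service
can be plugged in without touching the analysis. Similarities are
descriptive only. The quartile analysis bins pairs at the empirical
25/50/75 similarity percentiles (boundary values to the lower bin),
takes the median LR+ per bin (+∞ above all finite values), and applies
Kruskal–Wallis with mid-ranked ties and tie correction (chi-square,
df = 3). It runs on the combined stratum (all species, all modalities,
no exposure restriction) so each pair is scored once; by default only
significant pairs enter, switchable to all scored pairs. Fewer than 8
pairs, or tie-degenerate similarity distributions that empty a bin, are
reported as skipped rather than analyzed.

## Exposure control

Exposure comparability is |Δlog10 Cmax| ≤ δ or |Δlog10 AUC| ≤ δ with
δ = 1.0 by default (the 10-fold interspecies safety factor); the
boundary is inclusive and the metrics that satisfied the rule are
recorded. With repeated PK studies per (drug, species), the rule is
existential — one comparable animal/human record pair admits the pair —
which is the most permissive literal reading; geometric-mean or
strictest-pair aggregation are deliberate alternatives left as
switches. Drugs with no PK data leave the exposure-controlled subset
entirely; "no shared metric" is distinguished from a failed comparison.

## Target enrichment

True-positive drugs of a concordance result are annotated with their
on/off-targets (file-based, relation-filterable). Enrichment is the
upper-tail hypergeometric probability P(X ≥ overlap) per annotation set
(GMT format), each set intersected with the background first, with
Benjamini–Hochberg correction across sets and significance at adjusted
p < 0.01. The background defaults to all targets annotated to any
universe drug and is overridable — enrichment backgrounds must be
explicit to be reproducible. No interaction networks, clustering, or
pathway topology: this is a self-contained, file-based enrichment core.

## Synthetic cohorts

The generator emulates the statistical structure of curated
pharmacovigilance extracts without mimicking real drug names, term
text, or AE co-occurrence. Per drug and planted profile, the human
occurrence is Bernoulli(prevalence); given the human outcome, each
panel species shows the finding with probability sens (or 1−spec),
conditionally independently across species — the simplest structure
realizing a planted per-species LR+ = sens/(1−spec); cross-species
correlation is an extension hook. A profile may surface preclinically
under a different same-SOC term (a proxy), planting cross-term
concordance. Vocabulary terms carry preclinical/clinical observability
flags, giving partial overlap between the two sides' vocabularies.

Anchor records (one clinical-only and one preclinical-only anchor term
per drug, under an "Investigations"-style SOC) guarantee dual reporting
so planted cell fractions are not biased by universe churn; anchors are
one-sided, so identical-term mode never tests them, and their full
margins make them p = 1 in cross-term mode. Post-marketing/refuted
records are emitted as flagged duplicates of clean records (5% each by
default), appended after the clean copies so first-instance
deduplication always retains the clean record and preparation leaves
the planted truth intact.

PK exposures are lognormal: human log10 Cmax ~ N(0, 0.5) (μg/mL scale);
the animal-human log gap is N(d0, σ) with σ = `pk_sigma_log10`
(default 1.0) and d0 solved so that P(|Δ| ≤ 1) equals
`comparable_fraction_target` (default 0.5); an unreachable target is a
config error. AUC is Cmax times a per-drug duration factor shared by
the human and animal rows, so the AUC log-ratio equals the Cmax
log-ratio and the planted comparable fraction is exact under the OR
rule. Targets: each drug draws 2 background off-targets from a pool of
1000 decoys (sparse, genome-scale-like background), and a drug causing
an AE carries each of the AE's linked targets with probability 0.6
(different drugs engage different members of a target family). All
randomness derives from one root seed via fixed per-component spawn
keys (drugs, PK, targets, one stream per profile index), so appending
profiles never perturbs earlier draws and a fixed seed yields
byte-identical tables.

The generator does not emulate reporting biases, severity, dose
response, term co-occurrence, or real semantic structure in term text;
passing tests demonstrate correct recovery of the planted generative
model, not performance on real pharmacovigilance data.

## Pipeline and reproducibility

A run is one YAML/JSON config: either five input tables (CSV, RFC-4180,
with an optional column map and JSON schema sidecars) or a simulate
block, plus strata, thresholds (α_concordance = 0.05,
α_enrichment = 0.01, exposure δ = 1.0, low-TP = 5), output directory
and seed. Stages (simulate → prepare → exposure → concord → crossterm →
semantics → enrich → report) communicate through files and are
independently re-runnable via CLI subcommands. All writers sort rows by
key and serialize floats canonically (`Inf`/`NA` conventions), and the
manifest records the config hash (over analysis-defining fields; the
output path is excluded), seed, stage list, per-file row counts and
correction family sizes — identical config + seed reproduces
byte-identical outputs. Stage failures abort with a stage name and
machine-readable code (CLI exit codes: 2 config, 3 data, 4 stage).

Enrichment exemplars default to the top-2 significant identical-term
AEs by LR+ (distinct PTs, deterministic tie-break by TP count, SOC,
then term).

## Problem sizes used in validation

The validation suite exercises: the exhaustive Fisher sweep over all
46,375 tables with N ≤ 30 against strict same-margin enumeration;
10,000 random tables for the metric and odds identities; planted-LR
recovery at n = 2000 drugs over 20 seeds (estimate within [9, 15] of
the planted 12); 200 null profiles at n = 400 for calibration; 2000
drug–species pairs for exposure-fraction recovery (±0.05); 1000 planted
similarity/LR pairs with 100 permutations for the quartile trend; exact
rational enumeration of enrichment tails up to background 60 and 1000
random vectors for BH; and duplicate end-to-end runs at n = 200 for
byte-identity. These sizes were chosen so each check is decisively
powered by the corresponding closed-form or oracle computation.

## Known limitations

Binary presence/absence encoding (no frequency, severity, or dose
response); TN counts are estimates tied to the chosen universe
definition; the default embedding provider carries no semantics; the
two-sided Fisher dialect and the universe definition are explicit
switches that other implementations may set differently; identity
resolution does not arbitrate conflicting identifiers across cascade
tiers; no unit conversion beyond the declared Cmax/AUC units.
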