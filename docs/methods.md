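# Methods

## The data model

An annotation unit records one gene-expression-change mention: a sentence,
spans for the gene, the expression keywords and the cancer terms (0-based,
half-open, counted in Unicode code points), and the four concept values
CGE, CCS, IGE, PT. Two structural rules are enforced everywhere: CGE and
CCS are always annotated, and IGE/PT are skipped **iff** CCS is
"unidentifiable". The skip marker (`None` in memory, `null` in JSONL, an
empty TSV cell) is deliberately distinct from the value "unidentifiable":
the value is an annotator's judgment, the marker means the scheme never
asked the question. Conflating them would silently inflate the IGE/PT
denominators in every distribution table.

Validation returns violations as data (a list of descriptors) rather than
raising, so corpus QC can report all problems in one pass; serialization
and classification refuse invalid units.

The on-disk dialects (JSONL with offset spans; TSV with bracket-marked
sentences `[*…*]_g_ / _e_ / _c_`) are this package's own canonical formats:
they carry exactly the information content of the scheme, and
`parse(write(c)) == c` holds field-for-field in both. Dictionary-based
cancer-term tagging uses case-insensitive leftmost-longest matching with
token boundaries defined as maximal runs of letters/digits — the standard
greedy convention for disease-term dictionaries; scanning resumes after
each match, so matches never overlap.

## Gene classification

The ten built-in rules fix CCS (a rule only fires when the direction of
the cell-state change is known) and constrain the other three concepts or
wildcard them. `match_rule` asserts, rather than tie-breaks, uniqueness of
the match: mutual exclusivity is provable by enumerating all 2×5×4×2 = 80
complete tuples, and the test suite does exactly that.

`first_principles_class` re-derives the class without the table:

1. CCS unidentifiable or normal→normal → not related.
2. CCS normal→cancer: causality → oncogene (increased) / tumor suppressor
   (decreased); observation → biomarker.
3. CCS cancer→normal: claimed causality, or causality deduced from
   (IGE up-regulated ∧ CGE decreased) or (IGE down-regulated ∧ CGE
   increased) → oncogene (decreased) / tumor suppressor (increased);
   observation otherwise → biomarker.
4. CCS cancer→cancer: only an observed reversion of an initial deviation
   (the two deduced-causality patterns) marks a biomarker; otherwise not
   related.
5. IGE unidentifiable: evaluate 1–4 under each concrete IGE value and keep
   the class asserting the weakest relation
   (not_related < biomarker < oncogene = tumor suppressor).

A plausibility predicate marks the combinations a literature corpus would
essentially never contain: CCS = cancer→normal with a *concrete* IGE that
does not corroborate the change (no deduced causality). This predicate is
structural — it never consults the rule table — and enumeration confirms it
excludes exactly the eight classed tuples no rule covers, which makes the
equivalence between the derived and built-in tables a genuine check rather
than a tautology. `derive_rule_table` compresses the surviving tuples into
maximally wildcarded, mutually exclusive patterns per (class, CCS) group by
greedy exact cover, most general pattern first; on this scheme the cover is
unique and yields exactly ten rules.

Evidence aggregation groups classifications by (case-folded gene string,
cancer type) with no lexicon normalization: inferred classes are textual
evidence to be accumulated, not database assertions.

## Corpus statistics

* Integer percentages are computed by round-half-up in exact integer
  arithmetic; this is the convention the reference tables follow.
* Contingency tables drop never-observed rows/columns (normal→normal and
  cancer→cancer never occur) before testing, so degrees of freedom match
  the values in play. Tables involving IGE or PT require a CCS filter
  excluding "unidentifiable", since those units carry no IGE/PT value.
* The parenthesized cell diagnostics are **Pearson residuals**
  (O−E)/√E — verified to reproduce the published cells 2.65 and 6.30;
  adjusted residuals do not. Their squares sum to the chi-square statistic
  by construction, and the test p-value comes from `scipy.stats.chi2`
  (no continuity correction); `scipy.stats.chi2_contingency` serves as an
  independent oracle in the tests.
* Odds ratios are returned at full precision; the report-parity formatter
  *truncates* to one decimal (6.56 → 6.5, 7.87 → 7.8), which is the
  convention the published prose follows. The PT×IGE ratio is computed on
  the unchanged/unidentifiable columns only — the up-regulated column
  (counts 0 and 2) cannot enter a finite cross-product ratio. A
  Haldane–Anscombe +0.5 correction is available behind an explicit flag.
* The conditional-independence analysis is implemented as a
  Cochran–Mantel–Haenszel test (statsmodels `StratifiedTable`, 2×2×K, no
  continuity correction) of two binary concepts across CCS strata; strata
  with a zero margin are dropped and counted in the result metadata. The
  choice of CMH is this package's reconstruction of "marginal independence
  conditioned on CCS"; its calibration is verified by simulation (type-I
  error ≈ nominal α under the generator's conditional-independence null).
* p-values below 2.2e-16 are *displayed* as `<2.2e-16` (the conventional
  double-precision floor); the raw value is kept on the result object.
* One caution: the published claim that CGE is "four times more likely to
  be increased" under progression matches the within-stratum odds 318/79 ≈
  4.0, not the 2×2 odds ratio (≈ 6.8); the package reports the odds ratio
  and leaves such prose readings to the caller.

## Agreement metrics

Simple agreement is the fraction of identically labeled units. Cohen's κ
chance-corrects with the empirical marginals and is reported as an explicit
`UNDEFINED` (rendered "N/A") when expected chance agreement is 1 — the
degenerate single-category case that skewed concepts like IGE produce. The
G-index fixes chance at 1/k where k is the concept's **full pre-specified
category count** (CGE 2, CCS 5, IGE 4, PT 2), not the observed count; this
choice uniquely reproduces the reference agreement tables and is why G
stays informative where κ collapses.

Rule validation scores each unit against two independent human class
annotations: full (both equal the inferred class), one, or no match. The
per-rule agreement rate is (full + one)/total; the micro average pools all
records; the macro average is the unweighted mean over populated rows
*including* the no-rule row — with the reference per-row counts this
reproduces micro 95% and macro 89%. (The reference table's printed total
full-match count is internally inconsistent with its own column; column
sums are used.)

## Synthetic corpus generator

The generator emulates the published summary of the 821-unit reference
corpus. Defaults (all fixed, normalized printed counts — none of these are
free parameters):

* cancer-type proportions 310/255/256 (prostate/breast/ovarian);
* CGE×CCS joint = {318, 45, 204; 79, 76, 99}/821 over columns
  (normal→cancer, cancer→normal, unidentifiable) — the unidentifiable
  column carries the full 303-unit mass with its observed CGE split;
* IGE | CCS: (0, 0, 212, 185)/397 given normal→cancer and
  (2, 0, 0, 119)/121 given cancer→normal; skipped when CCS unidentifiable;
* PT | CCS: (311, 86)/397 and (43, 78)/121.

IGE and PT are drawn conditionally independently given CCS — the reference
analysis itself found no residual dependence among the remaining pairs once
CCS is conditioned on — and this choice reproduces the reference
rule-application shares within sampling error (rule 7 share
≈ 311/821 ≈ 0.379). Sentences are realized from a small template pool with
exact spans; no downstream operation interprets the free text, so template
realism is deliberately minimal. Randomness derives from one
`numpy.random.SeedSequence` split into named substreams (concept values /
surface realization / perturbation), so identical (config, seed) gives
byte-identical serialized output and extending one feature does not shift
another's draws.

The annotator simulator flips each annotated concept value with a
per-concept probability to a uniformly random *different* admissible value
(skipped concepts stay skipped), giving expected simple agreement 1 − f.
Default flip rates (CGE 0.01, CCS 0.21, IGE 0.02, PT 0.14) approximate the
observed disagreement levels per concept.

What the generator does **not** emulate: real sentence syntax, NER/event
extraction noise, per-cancer-type differences in the joint distributions
(only the pooled joints are published; per-type generation reuses them
scaled by the type proportions), and any dependence of IGE on PT beyond
what CCS induces. Passing tests on synthetic corpora therefore validate
the pipeline's statistical machinery and structural invariants, not
performance on real text.

## Problem sizes and numerical choices

Tests use synthetic corpora of 300–10,000 units; marginal-recovery checks
run at n = 10,000 where the binomial standard error justifies a ±0.02
band, and the CMH calibration uses 100 replicates of n = 1,500 with a
generous acceptance band around the 5% nominal rate. Probability vectors
must sum to 1 within 1e-9; agreement coefficients treat pe ≥ 1 − 1e-12 as
degenerate. Exit codes of the CLI: 0 success/clean, 1 validation or I/O
failure, 2 usage error.
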