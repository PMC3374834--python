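# Methods

## The analysis

A trial registry snapshot is a set of XML records, one per study. The
analysis asks how often sponsors deposit summary results and list outcome
measures, and whether that behaviour differs by the kind of institution
responsible for the trial. It proceeds in four stages.

**Sponsor classification.** The unit of classification is the lead sponsor
name, free text in many languages. Each of five institutional classes
(`edu`, `com`, `gov`, `hos`, `col`) owns a keyword dictionary; a name is
assigned to the highest-priority class whose keyword it contains. Names
are Unicode-compatibility normalised, case-folded, and whitespace-collapsed
before matching; diacritics are preserved so "Hôpitaux", "Klinik" and
"Università" match exactly (an optional diacritic-folding switch exists,
default off). Matching is at word boundaries — "Include" never matches the
suffix keyword "Inc.", which additionally matches with its dot elided at
end of name. Names matching nothing inherit a class from the registry's
own agency label: Industry → `com`, NIH and U.S. Fed → `gov`, Other →
unclassified. Unclassified records keep their place in corpus-wide
denominators but carry no per-class row.

The priority order is `hos > edu > com > gov > col`. Only the
hospital-over-university precedence is externally given ("University
Hospital" must count as a hospital); the remainder is this package's
choice, ordered so that specific facility terms beat generic corporate and
governmental terms, and is configurable. Ties within a class resolve to
the longest matching keyword, then lexicographically, making assignment
deterministic. The shipped dictionaries are a documented reconstruction —
a production analysis would refine them against its own corpus (the YAML
file is data, not code, for exactly that reason); no manual
post-correction step is included.

**Requirement cascade.** Results deposition is treated as mandatory for a
trial when six per-record conditions hold simultaneously: overall status
"Completed" with a completion date on or before the snapshot cutoff
(default 2011-12-31); affirmatively FDA regulated; affirmatively Section
801 covered; an explicit phase intersecting {2, 3, 4}; at least one
attached literature reference; study type "Interventional". Absent
oversight flags count as unmet — registry counts of regulated trials are
counts of affirmative assignments. A month-granular completion date is
"on or before the cutoff" only if its *latest* possible day is, so trials
that may have completed after the snapshot are excluded. The phase rule is
set intersection by default ("Phase 1/Phase 2" qualifies); a stricter
minimum-phase-2 variant is a switch. Reference screening by journal
membership is out of scope: any attached citation counts.

**Tables.** Every table cell is a triplet (count with results, count
total, percentage), with the percentage recomputed from the two integer
counts using exact decimal arithmetic and half-up rounding — never carried
through intermediate floats. Zero denominators render "n/a". A trial with
several intervention types counts once per type; a trial naming several
phases counts once per phase. Enrollment tables keep the registry's
sentinel values (0, 99999999) as-is in the unrestricted stratum: their
inflation of maxima and means is part of the observed phenomenon.

**Odds ratios.** For class-membership indicator Y and reporting indicator
X, the association is the cross-product odds ratio of the 2×2 joint
distribution, identical in probability and count form. The confidence
interval is the Woolf log-odds interval, `log OR ± q·SE` with
`SE = √(Σ 1/n_yx)`. The quantile `q` is a two-sided Student-t quantile
with n − 1 degrees of freedom by default; the source analysis states only
that a t distribution at the 95% level was used, without degrees of
freedom, so the conventional Woolf interval with a t quantile is this
package's interpretation, and a standard-normal switch is provided (the
two are indistinguishable at registry sample sizes). The published
interval widths for the full snapshot are far narrower than any Woolf-type
interval at those sample sizes and could not be reproduced by any standard
method; they are treated as unverifiable. Zero cells raise an error by
default — an infinite estimate is never returned silently — with an
optional Haldane–Anscombe +0.5 correction. The `col` class is excluded
from class-versus-rest comparisons (it overlaps the others), as are
unclassified records; both exclusions are configurable. The pipeline
driver falls back to the Haldane correction (recording that in its
manifest) when a small corpus produces a zero cell, and skips a report
whose class margin is empty.

## The synthetic registry

The generator emulates the marginal structure of the 2012 snapshot; each
default is traceable to a printed figure of that analysis:

| parameter | default | provenance |
|---|---|---|
| class mix | edu .272, com .321, gov .164, hos .145, col .084, uncl. .014 | published class counts / 118,602 |
| completed fraction | .556 | 65,937 completed / 118,602 |
| completion-year profile | 13,945 (2011) … 1,142 (≤2000) | yearly completed totals |
| FDA-regulated | .298 | 35,344 / 118,602 |
| Section 801 (within FDA) | .7105 | 25,151 / 35,344 → .212 marginal |
| interventional | .827 marginal | 54,544 / 65,937 completed |
| publications among completed | .0709 marginal | 4,675 / 65,937 |
| outcome ≥1 per class | .728 / .7742 / .3782 / .7674 / .7621 | per-class outcome rates |
| outcome >1 per class | .2394 / .2729 / .1124 / .277 / .3022 | per-class rates |
| restrained results per class | hos .3231, edu .0979, col .0930, com .3925, gov .0641 | restrained-pool deposition rates |
| unrestricted results per class | com .092, hos .014, edu .014, col .0105, gov .006 | results-bearing trials / class totals |
| treatment purpose | .60 | 70,929 / 118,602 |
| zero-enrollment rate | .0039 of completed | 255 completed trials |
| sentinel 99999999 rate | 4.5e-5 of completed | 3 completed trials |

Where the snapshot prints no value, the generator makes a one-time choice:
per-class phase mixes reproduce the published qualitative shape (companies
peak at phase 3, government and collaborations at phase 2, education has
more phase-4 than phase-3 trials); durations are 1 + Poisson(1.5) years;
enrollment is per-class log-normal with σ ≈ 1.5 and medians of a few
hundred participants; the non-completed status mix and the
anticipated-type violation rate among completed trials (15%) are chosen to
resemble a live registry. Requirement components are modelled with a
realistic dependence structure: regulated trials are interventional with
an explicit phase in 2–4, Section 801 coverage is nested inside FDA
regulation, and attached references concentrate in regulated completed
trials (rate .3158 there, .005 background — the two reproduce the .0709
publication marginal). This correlation mirrors the fact that registry
citations cluster in FDAAA-covered drug trials, and it gives the emergent
restrained pool (~3.7% of a corpus) enough mass for stable per-class rate
estimation; fully independent requirement draws would match the same
marginals but shrink the restrained pool several-fold.

Sponsor names are built from a class keyword plus neutral decoration
tokens verified to match no keyword, so keyword-named sponsors are
recoverable by construction; a configurable fraction of `com`/`gov`
sponsors (15%) and all unclassified sponsors get keyword-free names that
exercise the agency fallback. Ground truth (true class, requirement
status, reporting indicators) is emitted per trial. Each trial draws from
its own random generator derived by counter from the corpus seed, so a
corpus is byte-reproducible and insertion order never changes sampling.
Enrollment anomalies are injected by overriding sampled values, making
their rates exact parameters.

What the generator does **not** model: real sponsor-name distributions
(and hence typographic noise the keyword classifier would face in the
wild — classifier recovery on synthetic names is exact by construction,
so passing tests demonstrate the pipeline's correctness, not the
dictionaries' real-world recall); temporal autocorrelation beyond the
yearly profile; correlation between enrollment and reporting; collaborator
lists. Rates estimated from a synthetic corpus differ from the calibrated
inputs only by sampling noise.

## Problem sizes and numerical choices

Test and reproduction runs use corpora of up to 20,000 trials (three seeds
pooled for rate estimation, ~60,000 trials and ~2,200 restrained-pool
members) — large enough that binomial noise sits well inside the stated
comparison bands for corpus-wide rates, while restrained per-class rates
(pools of a few hundred) carry sampling standard errors of 1–3 percentage
points, which the 4-point comparison band absorbs. Confidence-interval
calibration uses 1,000 multinomial tables of size 500 drawn from a joint
with true odds ratio 2. Percentages are computed in decimal arithmetic and
compared at each value's own printed precision. Partial-date comparisons
always resolve missing granularity away from inclusion. CSV serialisation
is RFC 4180 UTF-8 and round-trips records exactly, as does the XML writer
against the parser.

## Known limitations

- The shipped keyword dictionaries and the priority tail are
  reconstructions; per-class counts on a real corpus will differ from any
  published classification, whose exact dictionaries and manual
  corrections are unrecoverable.
- The published full-registry odds ratios depend on an analysis pool whose
  exact definition is internally inconsistent across the source tables;
  only their qualitative ordering (companies highest, government lowest)
  is asserted here, and it is robustly reproduced.
- The registry dialect handled is the pre-2012 public XML; later schema
  revisions and JSON APIs are out of scope, as is downloading from the
  live registry.
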