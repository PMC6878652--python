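# Methods

This note documents the statistical model, the defaults and the design
choices behind `cghcall`, and what the synthetic-data experiments do and
do not demonstrate.

## Signal model and coordinates

A hybridisation produces one log2 test/reference ratio per probe of an
ordered design. Copy number c shifts the expected ratio of affected probes
by log2(c/2): +0.585 for a single-copy gain, −1.0 for a heterozygous
loss; a homozygous loss (c = 0) is represented by a finite floor of −4 —
far below every loss threshold while keeping arithmetic finite. All
intervals are 1-based fully closed; BED export (0-based half-open)
converts only at the I/O boundary.

## Noise and QC

**DLRS.** The per-sample noise metric is the derivative log ratio spread.
The package uses the standard robust definition

    DLRS = IQR(consecutive-probe differences) / (1.349 · √2)

pooled over chromosomes but never differencing across a chromosome
boundary. Under i.i.d. Gaussian probe noise of SD σ the differences have
SD σ√2 and IQR/1.349 estimates their SD robustly, so DLRS estimates σ;
calibration on 10,000-probe profiles recovers σ ∈ {0.1, 0.2, 0.3} to
within 0.01 on a 20-seed average. A single CNV of k ≪ n probes moves the
estimate by well under 5 % (IQR robustness). Samples with DLRS ≥ 0.3
(boundary inclusive) are flagged `replicate_required`.

**Centralization** subtracts the median log2 ratio (deterministic, robust
to small CNVs, idempotent). **GC correction** subtracts a least-squares
linear fit on the centred per-probe GC fraction; linear rather than loess
because it is the simplest model that makes injected-bias recovery
well-posed (slope 0.8 recovered to ±0.05 at n = 10,000). Applying
centralization and GC correction in either order changes final calls on
essentially no seeds; the DLRS gate is applied after correction.

## Segmentation

A candidate interval I scores S(I) = Σ_{i∈I} x_i / (σ√|I|), with σ the
sample's DLRS (overridable). Detection extracts disjoint per-chromosome
intervals with |S| ≥ 6 greedily: find the globally best-scoring interval
of the chromosome, record it, recurse into the flanking remainders. Ties
break by leftmost start, then shortest length. This is the classical
maximal-scoring-interval statistic behind commercial aberration-detection
methods; per-probe quality weights are not modelled (simulated data has no
probe-quality channel). The greedy extraction is verified to return
exactly the interval set of an exhaustive O(n²) search on seeded profiles
up to 200 probes. Scores are scale-equivariant (profile and σ scaled
together leave calls unchanged) and lowering the threshold never removes a
call.

Call boundaries record both the first/last aberrant probes (inner) and
the flanking normal probes (outer); the true breakpoint lies between
them. At a chromosome end the outer boundary collapses onto the inner one.

**Visual rescue.** The manual whole-genome review that accompanies
software calling is emulated deterministically: runs of ≥ 2 consecutive
probes all above +0.5 (gain) or all below −1.0 (loss) not already covered
by a software call are added with `source="visual"`. A human reviewer may
apply stricter implicit context rules; the emulation is therefore an
approximation, and visual calls stay distinguishable downstream.

## Curation

Software calls are retained with ≥ 2 probes and MALR > 0.30 (strict);
visual calls bypass the MALR filter, mirroring how the manual review is
run with the amplitude filter switched off. Nearby same-type calls
separated by ≤ 2 intervening probes merge into one CNV unless an
intervening probe opposes the call's sign at |log2| > 0.3 — opposing
intervening signal is read as evidence of two distinct events (the most
coherent reading of an ambiguous rule; recorded here rather than asserted
as the only one). Wider gaps always separate. The filter is a pure subset
operation and split/merge is idempotent.

Triage is a deterministic emulation of a human judgement with
configurable bands: *likely* when the mean ratio reaches the attention
thresholds (≥ +0.5 gain, ≤ −1.0 loss); *unlikely* when MALR ≤ 0.35 or a
2-probe call has |mean| < 0.4; *possible* otherwise. Triage labels calls
and never deletes them.

Replicate concordance: `confirmed` when a replicate array holds a
consistent call (the same rule as database matching); `not_excluded` when
a replicate merely trends the same way over the call's probes (matching
sign, |mean| > 0.15 — chosen as half the MALR filter); `not_confirmed`
otherwise; `not_evaluable` without a replicate.

## Database consistency and frequency tests

A call is consistent with a population record when both are the same kind
(gain/loss), the overlap covers ≥ 80 % of the call, and each side has at
most 2 differing probes counted on the array design. The overlap
denominator is the detected call (the unit being classified); a
reciprocal-overlap switch exists in the config. When the call's
probe-level ratios are known, its differing probes count only at
|log2| ≥ 0.3 — a quiet flanking probe is noise, not evidence of a
distinct event; database records have no probe ratios, so all their
differing probes count. Database boundaries have unknown probe coverage,
so probe counting uses this design as a proxy (stated in output
metadata). Matching is reflexive and the ≤2-probe criterion is applied
symmetrically.

Frequency bands: common > 5 %, rare ≤ 1 % (non-zero), intermediate in
between; calls with no (non-zero-frequency) match are novel. Case/control
carrier frequencies are compared with Fisher's exact test, switching to
the chi-square test with Yates continuity correction when all expected
cell counts reach 5 (the standard operationalisation of "when feasible").
Fisher p-values are computed from exact integer hypergeometric weights,
which makes tie handling exact and lets the test suite verify them to
1e-10 against an independent enumeration for every table with total ≤ 60;
scipy's implementation is used as an additional cross-check. Odds ratios
come from the 2×2 table, with the Haldane 0.5 correction applied (and
flagged) only when a zero cell makes the ratio undefined.

## Truth classification and summaries

A variant is **true** when any evidence channel supports it: a database
match at non-zero frequency, confirmation on a replicate array, or
orthogonal validation. Validation outcomes (qPCR, PCR, higher-density
array) enter as labels — wet-lab chemistry is out of scope. Novelty is
tracked separately: only matches above the rare band count as "on
database"; a variant matched only at ≤ 1 % is true via the database
channel yet counts among the novel variants in stratified summaries,
following how very rare database hits are conventionally tabulated.
Classification is monotone — adding evidence can only turn a variant
true.

The stratified summary counts patients once per column (analyzed / with
aberration / with true / true on database / true not on database), so the
two novelty columns may sum to more than the "true" column when a patient
carries both kinds. CNV sizes (outer_end − outer_start + 1) are compared
between groups with the two-sided Wilcoxon rank-sum test; the test is a
package choice — medians are the reported statistic, and no particular
test is canonical for this comparison.

The bundled reference cohort (`cghcall.datasets`) encodes a 59-patient
screen at the label level: the validation follow-up table individually,
and the non-carrier patients as synthetic fills reproducing the cohort's
marginal composition only (their joint attribute combinations are
arbitrary, and the summary statistics asserted on this cohort use
marginals and individually encoded carriers only).

## Inheritance

A parent transmits a child's variant when the parent's profile yields a
consistent call. Exactly one positive parent resolves the origin; two
tested-negative parents give de novo; both-positive is surfaced as
`ambiguous` rather than silently resolved; a needed-but-unavailable
parent leaves the origin unknown. The maternal share among inherited CNVs
is tested one-sided (upper tail of the exact binomial at p = 0.5; 7/7
maternal gives 0.5⁷ = 0.0078), with a config option for the two-sided
test, and the maternal proportion carries a two-sided 95 % Clopper–Pearson
interval (the closed-form k = n lower edge is (α/2)^(1/n), e.g. 0.590 for
7/7).

## Synthetic data: what it shows and what it does not

The generator reproduces the study conditions the pipeline targets: a
15K-style design (20 candidate regions with the published probe counts
and spacings, a 3,130-probe genome backbone laid proportionally to
chromosome length — the backbone's bp spacing is not specified anywhere,
so it is a parameter — and optionally 301 probes replicated ×5), planted
events of 2–15 probes up to multi-Mb, i.i.d. Gaussian probe noise
calibrated so measured DLRS ≈ the requested SD (default 0.15), optional
linear GC-coupled bias, replicate arrays, and trios in which inherited
CNVs are planted in exactly one parent and de novo CNVs in neither.
Locus anchors are GRCh37-style coordinates and the per-probe GC fraction
is simulated, not sequence-derived.

Deliberately not modelled: hybridisation chemistry, dye bias, scanner
artifacts, wave/autocorrelated noise, mosaicism, sex-chromosome baseline
shifts and probe-quality weights. Passing recovery tests therefore
demonstrates the correctness of the algorithms under the stated noise
model, not performance on real arrays, where correlated artifacts make
both false calls and replication failures more frequent.

Problem sizes used by the checked experiments (chosen to estimate each
rate stably): 50 single-sample cohorts on the full 15K design for
recovery/specificity, 20 seeds × 10,000 probes per σ for DLRS
calibration, 100 seeded profiles ≤ 200 probes for the exhaustive
segmentation oracle, every 2×2 table with total ≤ 60 for the Fisher
oracle, and 200 trios for origin recovery. The acceptance script runs
scaled versions of the same measurements (20 cohorts, 50 oracle profiles,
60 trios) and reports each value with its problem size.

## Degenerate inputs and numerical choices

DLRS needs ≥ 3 probes; constant profiles and strict linear ramps give 0.
Constant GC makes the GC fit degenerate: no-op with a warning. σ ≤ 0,
empty intervals, negative noise SD, zero cohort sizes, carrier counts
exceeding cohorts, copy-0 without a floor, and transmission tests with
zero inherited CNVs all raise errors. Segmentation ties break
deterministically (leftmost, then shortest); recomputation with identical
seeds is byte-identical, and every output file records the tool version,
config hash and seed.

## Known limitations

* Triage and visual rescue are deterministic emulations of human steps;
  they bound, but cannot reproduce, reviewer judgement.
* Database probe-difference counting uses this array's design as a proxy
  for unknown record boundaries.
* The uneven probe density across regions means genome-wide CNV burden
  comparisons are not meaningful on this design, and none are offered.
* Validation outcomes are inputs; the pipeline cannot adjudicate a
  discordance between a replicate and an orthogonal assay beyond the
  stated truth rule.
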