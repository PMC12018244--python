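# Methods

## The calling procedure

The unit of analysis is one paired group: a treated sample and its matched
control, measured on the same probes. For probe *i* with betas β_t, β_c:

- npCV_i = MAD({β_t, β_c}) / median({β_t, β_c}) = |β_t − β_c| / (β_t + β_c),
  defined as 0 when both betas are 0 (and hence when the pair is
  identical). The IQR/median variant equals 2 × MAD/median for a two-value
  set; because the next step is a rank filter, the two variants select
  identical probes. Both are exposed (`cv_method`), MAD/median being the
  default.
- The group's retention cut-off is the `cv_quantile` (default 0.75)
  quantile of {npCV_i} over **all** probes of the filtered matrix, computed
  with linear interpolation (type 7, the R/numpy default). Retention is
  inclusive (npCV ≥ Q3), so boundary ties are kept; an exclusive mode is
  available. The inclusive quantile rule provably selects the same probes
  as "top ⌈n/4⌉ by explicit rank, ties at the boundary retained", and the
  test suite enforces that equivalence against an independent rank-based
  oracle on tie-heavy random matrices.
- A retained probe is a dmCpG when |Δβ| > `delta_threshold` (default 0.2),
  strict inequality. Direction: Δβ = β_t − β_c < 0 is *hypo*, > 0 is
  *hyper*.

Groups are fully independent: nothing computed in one group (including its
Q3 cut-off) influences another; a dedicated test perturbs one group's
samples and asserts invariance of the others' calls.

Numerical choice: npCV values are rounded to 12 decimals before ranking.
Mathematically equal statistics can differ in the last ulp depending on the
division path (e.g. 0.3/0.5 vs 0.75/1.25), and a rank filter must not break
ties on that noise. 12 decimals is far below any scientifically meaningful
difference in a beta-derived ratio and far above double-precision noise.

## Preprocessing

Betas are assumed already normalized; within/between-array normalization is
out of scope by contract. Supplied utilities follow array conventions:
β = M/(M+U+offset) with offset 100 (the Infinium default; the offset is a
parameter because conventions differ), M = log2(β/(1−β)) after clipping β
into [ε, 1−ε] with ε = 1e−6 to stay finite at fully (un)methylated probes.

Probe filtering removes, in order: probes failing detection (p >
`detection_p_max` = 0.01 in **any** sample), SNP-blacklisted probes, probes
on chromosome X or Y, cross-reactive-blacklisted probes. Attribution is
first-rule-wins so the removal tally plus survivors always equals the input
count. Blacklists are consumed as plain id lists — their curation is
upstream of this package.

The variable-probe screen keeps rows with sd/|mean| > `var_ratio_threshold`
(default 0.5, strict), sd with ddof = 1. It is applied to M-values, which
are signed, hence the absolute mean in the denominator; rows with |mean|
below machine tolerance are excluded and counted rather than passed through
with an ill-defined ratio. Sample-relationship PCA runs on the M-values of
the selected probes, probes centered, samples as observations.

## Synthetic data

`simulate_study` emulates the target design: G groups (default 3, names
a/b/c), one treated + one control sample each, and per group
`n_planted_hypo` + `n_planted_hyper` probes (default 50 + 50) carrying a
beta-scale effect of `effect_size` (default 0.3) in the treated sample
only. Generation is additive on the logit scale and inverse-logit maps
everything strictly into (0, 1):

logit(β) = baseline_i + shift_{g,i} + treatment_{g,i} + ε,  ε ~ N(0, `noise_sd`²)

- baseline_i: three-component mixture (logit-normal around −2.2, +2.2, 0)
  giving the usual bimodal beta landscape;
- shift_{g,i} ~ N(0, `subject_shift_sd`²), drawn per group **and** per
  probe: donor pools differ probe-wise, and this is what makes samples
  cluster by group rather than by treatment. The default 1.5 (logit units)
  dwarfs the default noise 0.1, matching the regime where subject identity
  dominates;
- treatment_{g,i} is the probe-specific logit increment such that the
  pre-noise treated beta equals the pre-noise control beta ± `effect_size`
  exactly — i.e. planted Δβ is exact on the beta scale before noise.
  Control betas of planted probes are clipped away from the boundary
  (margin 0.02) so the shifted value stays inside (0, 1).

Planted hypo and hyper sets are disjoint within and across groups except
for a deliberate shared core: `shared_fraction` (default 0.25) of each
group's planted probes are common to all groups, so multi-group
intersection is exercised with known overlap. The truth object records the
planted Δβ per (probe, group) — exactly 0 for nulls — and the gene-level
projection of planted probes.

`simulate_expression` assigns each gene carrying planted methylation the
direction given by a concordance rule keyed on (region class, methylation
direction) — default: body-hypo → up, everything else → down — inverted
with probability `flip_fraction` (default 0.1), with adjusted p drawn below
the significance cut-off; all other manifest genes draw adjusted p at or
above it. A gene with several planted combinations uses its
lexicographically first one, a deterministic tie-break.

What the generator does **not** emulate: probe-wise heteroscedasticity,
spatial/array batch structure, detection failures beyond a uniform stub,
type I/II probe chemistry differences, and correlated probes within CpG
islands. Passing benchmarks on this generator therefore demonstrate the
procedure's correctness and its behavior under the stated noise model, not
performance on raw production arrays.

Benchmark conditions used by the test suite: 1000 probes, 300 genes,
50 + 50 planted per group, effect 0.3, logit noise 0.1, 20 seeds for
recovery (observed sensitivity ≥ 0.99, false-discovery proportion 0 at the
default thresholds; asserted at ≥ 0.9 / ≤ 0.1), 10 seeds for the PCA
structure check. These sizes keep the default suite fast while leaving wide
margins to the asserted bounds.

## Annotation and intersection

Region classing is exact and closed: TSS200/TSS1500/5′UTR → promoter,
1stExon/Body/3′UTR/ExonBnd → body, anything else is an error — no silent
default. A probe annotated to several (gene, region) pairs contributes to
each; a probe's direction is never aggregated against another probe's, so
a gene can legitimately hold both a hypo and a hyper record in the same
region class. Gene symbols match case-sensitively as given.

The Venn partition is exact and exclusive (cells indexed by the membership
subset; reconstruction of the inputs is a tested round-trip). "Common"
genes pool cells of subset size ≥ `min_groups_common` (default 2) across
all strata; a gene common in two strata counts once in the distinct total
but keeps both records, and the deG join then yields one row per stratum
record. deG symbols appearing with conflicting directions are reported and
excluded, never resolved silently.

## Over-representation

One-sided hypergeometric upper tail P(X ≥ k) with N = |universe|,
K = |set ∩ universe|, n = |query|, BH adjustment across tested sets,
significance at adjusted p < `enrich_alpha` (default 0.05). Only
over-representation is tested. The universe is the analysis's single most
consequential free choice and is therefore a required CLI argument; the
library defaults to all manifest-annotated genes only inside the results
object, where the manifest is known. Set-size limits (`min_size`,
`max_size`) apply to the annotated size K; none are imposed by default.

## Pipeline

`run_pipeline` executes preprocess → call_dm → annotate → intersect →
integrate → enrich from one YAML/JSON document with unknown keys rejected
before any stage runs. Integrate and enrich activate only when a deG table
or GMT collection is configured. Every stage writes a plain-text artifact;
`from_stage` resumes from those artifacts and reproduces downstream outputs
byte-identically (tested). The run summary echoes the effective parameter
set, SHA-256 digests of all inputs and the configured seed.

## Known limitations

- The npCV ranking has no error model; the Q3 quantile is a fixed-fraction
  screen, not an inferential threshold, and the procedure reports no
  per-probe p-values by design.
- With a single pair per group, hypo/hyper asymmetry of technical origin
  cannot be distinguished from biology.
- The gene projection trusts the manifest; no coordinate-based
  re-annotation or lift-over is performed.
- Enrichment results depend on the gene-set release and the universe
  choice; the machinery is deterministic but the catalogs are inputs.
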