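# Methods

## Scope

`surfrank` implements the computational core of a cell-surface
therapeutic-target screen: annotation-based shortlisting, multi-dataset
rank aggregation, and single-cell co-expression module extraction, plus
the gated statistical comparisons used to report contrasts. It does not
re-implement the published-tool stages that normally surround such a
screen — clustering/UMAP/integration/doublet detection of a Seurat-style
workflow, ontology enrichment services, or survival analysis. The module
outputs (disjoint case/control gene modules as TSV) are the inputs those
external steps consume.

## Shortlisting filter chain

Six pure per-gene predicates applied sequentially; a gene is excluded at
the first failing stage and the audit records stage and reason.

| stage | rule (defaults) | rationale |
|---|---|---|
| brain | brain regional distribution must be `not_detected`; `unknown` excludes | neurotoxicity of brain-expressed antigens |
| lung | lung NX ≤ 1.5 (exclusion is strictly "above") | pulmonary on-target, off-tumor toxicity |
| tissue distribution | not `detected_in_all` / `detected_in_many` | broad normal-tissue expression |
| tumor FPKM | cancer FPKM > 50 (strict) | the target must be high in tumor |
| surface localization | unique top-confidence site = `plasma membrane`, no `extracellular` tie, non-empty annotation | true surface residence; extracellular tie marks secretion |
| blood | not detected in blood by MS | shed antigen decoys the therapeutic |

Decisions where the procedure was genuinely open:

* **Missing lung NX passes (with a warning).** Consensus atlas tables
  always carry a lung column, so absence marks a partial or synthetic
  table; we do not exclude on absent evidence. By contrast a missing
  tumor-FPKM entry fails the FPKM stage, because that stage's rule is an
  inclusion requiring a value above a cutoff.
* **Any confidence tie at the top fails the surface stage**, not only a
  tie with `extracellular`: "top site with the highest confidence" is
  read as requiring a unique top. Exact NX values at the 1.5 boundary
  pass (the exclusion reads "above 1.5").
* Because the predicates are per-gene and independent, the final survivor
  set is invariant to stage order (property-tested); only the audit trail
  depends on it. The localization and blood checks are separate stages so
  audits show both intermediate counts.

Applied to a real Human Protein Atlas v20.1 export (not shipped), this
chain is documented to take a 12,948-gene liver-cancer transcriptome to 8
surviving genes via 1,246 → 731 → 585 → 99 → 10 intermediate counts;
packaged tests instead verify exact recovery of planted labels on the
synthetic 1,000-gene fixture.

## Rank aggregation

Per dataset, candidate genes are ranked by **median** expression in case
samples only (medians are robust to the heavy right tails of expression
data; even counts average the two central order statistics). Rank *k*
(ascending) maps to rank score RS = 0.1·k, so eight candidates span
0.1–0.8. Normalized score NS = RS / max RS makes datasets comparable
regardless of candidate count. Aggregation:

x̄_T = mean transcript NS, x̄_P = mean protein NS,
**x̄_TP = (m·x̄_T + n·x̄_P)/(m+n)**,

i.e. each dataset carries equal weight regardless of modality. With one
protein dataset, x̄_P is that dataset's NS.

* **Ties** share the mean of their tied ranks' scores (0.35 for a
  two-way tie over ranks 3–4 at step 0.1). This conserves the RS sum and
  makes results independent of input order; the tie rule is checked
  against explicit enumeration of both tie resolutions in tests.
* **Rounding** for display is half-away-from-zero at 3 decimals
  (0.5625 → 0.563); ordering always uses unrounded values.
* The statistic is scale-invariant per dataset (only ranks enter) and
  monotone in any single gene's median; both are property-tested.
* A candidate absent from a dataset's platform is dropped from that
  dataset's ranking with a warning, and — since aggregation requires
  presence everywhere — from the aggregate, mirroring how genes missing
  from an assay platform are handled in practice.
* One published reference table prints a transcript mean of 0.580 for a
  row whose own rank scores give 0.583; the arithmetic here yields 0.583,
  and the discrepancy is documented rather than reproduced.

## Single-cell correlation modules

QC is a **single fixed-order pass**: (1) drop features present in < 200
cells; (2) drop cells with < 500 expressed features or zero total count;
(3) compute per-cell mitochondrial percentage on surviving genes, pooled
over all cells, and drop cells above the 99th percentile. After cell
removal a surviving feature may fall below the stage-1 support threshold;
the contract is that each stage's rule held when it ran (no iteration).
Mitochondrial flags come from a sidecar column when present, else a
gene-symbol prefix (default `MT-`).

Normalization is per-cell library-size scaling to 10,000 followed by
log1p. Correlations are Pearson, computed on the log-normalized values
(normalization precedes all downstream analysis in the workflow this
package supports), separately within case and control cells, after
excluding cells with zero **raw** target count in that group — the
statistic describes co-variation where the target is actually expressed.
Genes with zero variance in the retained cells have undefined r and are
omitted.

Module resolution at cutoff r ≥ 0.6 (`>=` by default; a strict `>` mode
is exposed): a gene above the cutoff in both groups is assigned to the
group with the higher r; an exact tie goes to neither (warning). The two
modules are therefore disjoint by construction, and this is asserted, not
assumed.

## Gated group comparisons

Shapiro-Wilk at the same alpha as the main test (default 0.05, two-
tailed) gates every comparison: all groups normal → t-test (two groups)
or one-way ANOVA with Holm-Sidak-adjusted pairwise t-tests; otherwise
Mann-Whitney or Kruskal-Wallis with Dunn's pairwise z-tests (standard
tie-corrected rank-sum formula, implemented here) under the same
Holm-Sidak step-down. If exactly one of two groups is non-normal the
nonparametric path is taken. Constant groups are treated as non-normal
(Shapiro is undefined on zero variance). Type-I error of the gated
two-group procedure is calibrated in tests: 0.05 ± 0.02 over 1,000 null
simulations.

## Synthetic data

The generators reproduce the statistical structure the pipeline consumes,
not tumor biology — no pathway structure, cell-type composition, batch
effects, or ambient RNA. Passing tests therefore demonstrate correctness
of the algorithms under their stated models, not performance on real
cohorts.

* **Annotations**: every field is sampled so each predicate evaluates
  exactly to a planted per-stage label; surface-stage failures rotate
  through the three failure modes (extracellular tie, wrong top site,
  empty annotation). Default random labels follow the funnel shape of a
  genome-wide screen (pass rates 0.10/0.60/0.80/0.17/0.10/0.80 per
  stage), with one guaranteed all-pass gene and one exclusive failure per
  stage.
* **Bulk**: gene ranked *k* in the planted order has case median
  location `base_median · e^k`; samples are that location times
  log-normal noise (σ = 0.4 on the log scale). The log-gap of 1 between
  adjacent locations dwarfs the sampling error of a median at n ≥ 35
  (s.e. ≈ 1.25·σ/√n ≈ 0.08), so the empirical order equals the planted
  order with probability well above 0.999. Controls sit e² below cases,
  a large, clearly detectable shift. At σ = 0 the medians equal the
  locations exactly.
* **Single cell**: negative-binomial counts (gamma-Poisson, shape 6)
  around per-gene baselines that vary log-normally (σ = 0.3) around a
  mean of 4; the target gene's baseline is 50 — the regime of interest is
  a highly expressed target, and a low-expressed target would confound
  the planted zero-target fraction with stochastic dropout. In case cells
  only, the target and the 20 module genes share a standard-normal
  per-cell latent factor; the common loading is calibrated by bisection
  on a pilot simulation, measured the way the pipeline measures it
  (log1p counts, zero-target cells excluded), until the pilot correlation
  matches the requested `module_rho` (default 0.8). Library-size
  normalization in the full pipeline attenuates the measured r slightly
  (typically to ≈ 0.70–0.75 at a planted 0.8) because the module
  covaries with the cell total; the recovery margin over the 0.6 cutoff
  absorbs this, and recovery tests at three seeds require sensitivity
  ≥ 0.95 with ≤ 1% false positives. A configurable fraction of cells
  (default 10%) has the target count forced to zero to exercise the
  exclusion rule.

All generators are pure functions of their configuration including the
seed; identical configs give byte-identical outputs.

## Problem sizes in tests

Unit and property tests run on small instances (≤ 6 genes, ≤ 4 datasets,
≤ 1,000 annotation rows). The oracle-equivalence check uses 200 random
ranking instances against an independent sort-based implementation at
1e-12. Module-recovery tests use the generator defaults (500 genes,
2,000 case + 2,000 control cells) at three seeds; the null-calibration
test uses 1,000 two-group datasets of n = 30 per group. These sizes were
chosen to exercise every code path with comfortable statistical margins
while keeping the full suite around ten seconds on one CPU.

## Known limitations

* The filter chain is only as good as its annotations; `unknown`
  categories are excluded at the brain stage by design, which is
  conservative for discovery.
* Rank scores discard effect magnitude: a gene narrowly ahead in every
  dataset scores the same as one far ahead. The statistic is meant for
  choosing among a small shortlist, not genome-wide screening.
* Pearson correlation on log-normalized counts under-estimates latent
  co-expression at low expression; module membership near the cutoff is
  sensitive to sequencing depth.
* The QC pass is deliberately non-iterative; post-hoc feature support is
  not re-enforced after cell removal.
* Dunn's adjustment here is Holm-Sidak over the pairwise z-test
  p-values; software that applies a plain Bonferroni multiplier will
  give slightly more conservative pairwise p-values.
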