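# Methods

This note documents the models and numerical choices behind `delgem`, what
the synthetic study conditions emulate, and what passing tests do and do
not demonstrate about real screening data.

## The workflow

A campaign expands a validated DEL hit (the *reference binder*) into a
purchasable catalog. Initialization takes the `n_init` catalog members most
similar to the reference (Tanimoto over radius-3/2048-bit binary Morgan
fingerprints) and scores them. Each cycle then: (1) selects the top `k_top`
of the current seed set by score; (2) fine-tunes ("biases") the generative
model on them; (3) samples `n_generate` de novo molecules, keeping the
valid, canonically deduplicated ones; (4) scores them; (5) uses the top
`k_top` generated molecules as similarity queries into the catalog index;
(6) unions the per-query top hits (keeping each id's maximum similarity,
capped at `n_catalog_hits`); (7) scores the hits; and (8) nominates the
best `n_nominate`. Nominations plus the scored catalog hits of a cycle form
the next cycle's seed set (`carry_forward="nominations+hits"`; a
nominations-only mode exists). Ids nominated in earlier cycles are excluded
from later hit lists by default, so cycles nominate disjoint purchasable
sets.

Desk-scale defaults (`CampaignConfig`): catalog ~20,000, `n_init=2000`,
`k_top=100`, `n_generate=5000`, `n_catalog_hits=500`, `n_nominate=50`,
`n_cycles=2`. These preserve the stage ratios of production-scale runs of
this kind of workflow (million-member initialization, top-1K biasing sets,
100K generated, 10K catalog hits, 1K nominations) at roughly 1/100 scale,
sized so a full campaign runs in about a minute on one CPU once the model
is pretrained.

## Scoring

Scores follow the docking convention (lower = better); every selection
sorts ascending with ties broken by canonical SMILES, making ranking
deterministic. The surrogate objective is

    s(m) = -(w_sim * T(fp(m), fp(ref)) + w_qed * QED(m))
           + w_size * max(0, MW(m) - cap) / 100

with defaults `w_sim=10`, `w_qed=5`, `w_size=1`, `cap=500` g/mol. It is a
deliberately simple stand-in for structure-based docking that preserves the
two properties the pipeline's control flow depends on: it is strictly
improving in similarity to the reference (so the planted catalog
neighborhood is discoverable), and it couples in drug-likeness (so biasing
has a property gradient as well as a similarity gradient). `w_sim_anneal`
multiplies the similarity weight each cycle; values below 1 shift later
cycles toward diversity. Real docking plugs in through
`external_scorer_adapter` (input `.smi`, output `id,score` CSV, `{input}`/
`{output}` command template); molecules the scorer fails on carry a `+inf`
sentinel and are excluded from top-K selection but retained in reports.

The surrogate is *not* a binding model: scores have no physical unit and
absolute values are not comparable across different references or weight
settings.

## DEL seeding

Per-replicate enrichment is the observed/expected ratio
`count / (total_reads / library_size)` — 1.0 means a member was read
exactly as often as uniform sampling predicts. Replicates aggregate by
geometric mean, chosen over the arithmetic mean because DEL read counts
are Poisson-noisy and a large count in a single replicate is weak evidence:
the geometric mean sends any member with a zero replicate to zero rather
than averaging the spike away. The optional synthon view pools member
enrichments by building-block position with an arithmetic mean (pooling
across members is an averaging, not a replication, operation). The
enrichment statistic itself is a documented stand-in: production DEL
informatics pipelines apply normalizations (e.g. against no-target
controls) that require data this package does not model.

## The generative model

A single-layer GRU over SMILES tokens (embedding 48, hidden 128, ~120K
parameters), implemented in numpy with explicit backpropagation through
time and Adam (`lr=3e-3` pretraining, `1e-3` biasing, gradient-norm clip
5). Tokenization uses the standard SMILES regex — bracket atoms, `Cl`/`Br`,
`%nn` ring labels and stereo marks are single tokens — and every corpus
string must round-trip exactly. The vocabulary is frozen at pretraining;
biasing-set molecules with out-of-vocabulary tokens are skipped with a
warning.

Sampling is temperature-1.0 ancestral sampling, advanced for all `n`
sequences in one batch, capped at `max_len=120` tokens. Invalid samples are
discarded, not repaired — the validity rate is itself a useful training
diagnostic and repair would bias the output distribution. Duplicates are
removed by canonical SMILES, keeping the first raw-sample index.

The architecture is intentionally small: the workflow's contract is the
pretrain/bias/sample interface, and the scoring and language-model
components are designed to be substitutable. On the 5,000-molecule
fragment-grammar corpus, 10 epochs of pretraining (~40 s single-threaded)
reaches ~85–90% sampling validity; the test suite asserts the weaker ≥50%
bound at 8 epochs. Biasing defaults to 15 epochs on the top-K set — enough
to shift the sampling distribution measurably without collapsing onto the
biasing set (the suite bounds verbatim reproduction at ≤50% of samples).

Determinism contract: weight initialization, data shuffling, and sampling
all derive from explicit integer seeds; the pipeline derives per-stage
seeds from the master seed as `(master * 1000003 + cycle * 10007 + offset)
mod 2^31` with fixed offsets (pretrain 1, bias 3, sample 4), so single
stages are re-runnable in isolation and a repeated campaign is
bit-identical on the same platform/BLAS.

## Catalog search

Fingerprints are stored packed (uint8) with per-row popcounts; Tanimoto is
computed with vectorized hardware popcounts. Top-N search applies the
Swamidass–Baldi bound — for query popcount `q` and row popcount `p`,
`T ≤ min(p,q)/max(p,q)` — scanning rows in decreasing bound order and
stopping once the bound falls below the current N-th best similarity. The
bound only ever skips rows that cannot enter the result, so pruned search
is exactly the exhaustive scan (a test asserts equality against an
independent set-arithmetic oracle). Ties in similarity break by id. Batch
queries union per-query results keeping each id's maximum similarity.
Index construction streams its input and is persistable to a single `.npz`
(ids, SMILES, packed rows, popcounts, fingerprint config); rebuilds are
bit-identical.

## Hit characterization

- **Novelty**: per-molecule Tanimoto to the reference under the campaign
  fingerprint configuration, plus the maximum. One fingerprint
  configuration is used everywhere (initialization, search, novelty) —
  nothing in the workflow motivates mixing dialects.
- **Property comparison**: two-sample two-tailed t-test on one descriptor
  between two nomination sets. Welch (unequal variance) is the default —
  nomination sets from different cycles have no variance-equality
  guarantee — with the pooled Student variant exposed, since published
  figures often do not state which was used.
- **Embedding**: t-SNE (scikit-learn, PCA init, single-threaded) on raw
  fingerprint bits; deterministic per seed; row order preserved.
- **Dose-response**: 4PL `y = b + (t-b)/(1+(c/IC50)^h)` fit by bounded
  least squares (`scipy.optimize.curve_fit`), optimizing log10(IC50) for
  conditioning, initialized from the response extremes and the
  half-signal concentration, Hill slope bounded to [0.05, 10]. Standard
  errors come from the covariance diagonal (delta method for IC50). Fits
  whose observed response span is under 30% of the fitted asymptote range
  are rejected as unconstrained. Replicate IC50s report as arithmetic
  mean ± SD of per-replicate fits, the convention for replicate
  displacement assays.

## Descriptors

MW, heteroatom count, and rotatable bonds (non-ring single bonds between
non-terminal heavy atoms, amide C–N excluded) follow the standard RDKit
definitions; QED uses the original weighted-mean desirability weights. The
SA score uses the canonical published fragment-contribution table shipped
with RDKit's `Contrib/SA_Score` rather than a table re-derived from this
package's corpus: absolute SA values are therefore comparable with the
wider literature, at the cost of the fragment table reflecting general
medicinal chemistry rather than the fixture grammar. Multi-fragment
(salt) inputs keep the largest fragment before any descriptor or
fingerprint computation.

## Synthetic study conditions

`fixtures` generates every input the workflow consumes, as a pure function
of a seeded spec:

- **Catalog**: molecules assembled from a frozen fragment grammar (12 ring
  cores × 9 linkers × 16 caps, joined via RDKit `molzip`), guaranteeing
  chemical validity by construction. `n_planted` actives decorate the
  reference scaffold (a methyl-piperazine benzamide, the kind of chemotype
  recognized by methyl-lysine reader pockets) with up to two linker units
  and a cap, accepted when their Tanimoto to the reference falls in the
  planted band (default [0.35, 0.6]: reachable by similarity expansion,
  distinct enough to exercise novelty metrics). Planted ids are emitted in
  a truth table.
- **DEL counts**: per-replicate counts are Poisson with mean 20 reads per
  member (so expected totals are ~20× library size); planted members'
  means are multiplied by the enrichment factor (default 10×, 2
  replicates).
- **Dose-response**: 4PL curves on a log dilution series spanning ±2
  decades around the true IC50. `noise_sd` is a coefficient of variation
  (responses are multiplied by `1 + N(0, noise_sd)`), matching how
  plate-reader signal noise scales with intensity; at 5% CV and 8 points,
  single-curve IC50 recovery has a median absolute log10 error of ~0.035.

What the fixtures do **not** emulate — and hence what green tests do not
show about real data: real catalog chemistry (make-on-demand synthon
spaces are vastly more diverse than a 2,000-way grammar), DEL-specific
artifacts (barcode errors, sequence-dependent PCR bias, no-target-control
structure), structure–activity relationships beyond
similarity-to-reference, and assay pathologies (compound aggregation,
signal interference). The pipeline-level results on fixtures demonstrate
control-flow and estimator correctness, not prospective screening
performance.

## Known limitations

- The GRU's vocabulary is corpus-derived; a biasing set with exotic atoms
  absent from the pretraining corpus is partially skipped.
- Bit-identical reproducibility holds per platform/BLAS build; across
  different BLAS libraries, floating-point summation order may differ.
- The catalog index is held in memory; the streamed build keeps peak
  memory at one fingerprint row, but search assumes the packed matrix
  fits in RAM (~0.26 GB per million members at 2048 bits).
- `embed_2d` is for visualization; t-SNE distances are not calibrated and
  the cluster-preservation test is a sanity check, not a guarantee.
- 4PL fitting assumes responses are normalized signal fractions; raw
  fluorescence counts should be normalized upstream.
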