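# Methods

This note records the models behind `magpop`, the defaults and why they were
chosen, what the synthetic communities do and do not emulate, and the
numerical conventions that matter for reproducibility.

## Depth and TAD

Per-base depth is computed from gapless subject intervals with difference
arrays (equivalent to a per-base counting loop, which the tests assert).
The truncated average depth concatenates all contigs of a bin — zero-coverage
positions included, since absent regions are evidence about the population,
not missing data — sorts the vector and drops `floor(((1-q)/2)·L)` positions
per tail before averaging. The floor is an explicit convention (trimming is
otherwise ambiguous for fractional counts) and is guarded against binary
float noise (`(1-0.8)/2·10` is `0.999…` in IEEE arithmetic). `q = 0.8`
(TAD80) is the conventional default; `q = 1` degrades to the plain mean.

## Identity histograms and the population cutoff

Recruited aligned bases are binned by percent identity over [70, 100] in
0.5-point bins; a value exactly on an edge belongs to the upper bin and 100
to the top bin, which makes tie handling deterministic. Depth per bin is
bases divided by genome length.

The sequence-discrete cutoff automates a visual rule: recruitment collapses
by ~3 orders of magnitude between the in-population peak and the next
cluster. Scanning from the peak bin toward lower identity, the boundary is
the lower edge of the last bin with depth ≥ `peak · 10^-drop_orders`
(default 3.0) before the first sub-threshold bin. Two semantics are offered
for what counts as a *discontinuity*:

* default (`require_resumption=True`): the gap must be followed, at lower
  identity, by signal that climbs back above the threshold. A boundary
  separates two things; a unimodal histogram whose binomial tail simply dies
  out reports `discontinuity_found=False` and returns the configured floor
  (default 95%). This is the behaviour a co-recruiting sister clade produces
  and the one the recovery experiments assert.
* `require_resumption=False`: any sub-threshold bin ends the scan and is
  reported as a found boundary, even with nothing beyond it — useful when
  the histogram is known to be truncated.

A manual override (`cutoff_override` in the pipeline) bypasses detection
entirely, since practitioners sometimes fix the cutoff (e.g. at 98%) across
a study.

## ANIr

ANIr averages the identity of alignments at or above the cutoff. The default
weights each alignment by its aligned length (a base-level average, so long
and short alignments contribute proportionally); an unweighted per-read mean
is available because the field's usage is ambiguous between the two. With
gapless equal-length reads the two coincide in expectation. No qualifying
alignment raises an explicit error — an ANIr of 0 would be a lie.

## Marker-normalized abundance

The pooled depth of a universal single-copy gene is total aligned bases of
(already filtered) marker reads divided by the mean reference gene length;
the mean keeps the denominator a single scalar regardless of how many
reference variants are pooled. Abundance is TAD80 over that depth; zero
marker depth is an error, not infinity. Detection uses a strict `>`
at 0.01% (1e-4). Prevalence percentages are *truncated* (not rounded) to one
decimal — 25/38 → 65.7% — matching how such fractions are conventionally
printed; truncation and rounding differ only in the last decimal and the
package treats the printed convention as the contract.

Size-fraction enrichment is deliberately a plain classifier, not an
inferential model: per-sample proportions are averaged within each fraction
and compared as `log2((m_small+p)/(m_large+p))` with pseudocount `p` = half
the smallest nonzero proportion observed. Thresholds default to +2 (small-
fraction enriched, i.e. >4-fold) and −1 (large-fraction enriched). The
log-ratio is antisymmetric under swapping the tables, which the tests
assert; shrinkage/dispersion modelling of count noise is out of scope.

## MinHash sketches and ANI

Sketches are the `s` smallest (default 5000) splitmix64 hashes of distinct
canonical k-mers (k = 21, canonical = lexicographic minimum of a k-mer and
its reverse complement on the 2-bit alphabet; windows containing N are
skipped). The hash function is fixed and recorded in the output so sketches
are comparable across runs and machines.

Jaccard `j` is estimated on the bottom-s of the merged sketches. With
`w = 2j/(1+j)` the shared k-mer fraction, two transforms to ANI are offered:

* `binomial` (default): `ANI = 100·w^(1/k)`. Under the substitution-only
  divergence model `E[w] = (1-d)^k`, so this inversion is unbiased in `d`.
* `mash`: `ANI = 100·(1 − D)`, `D = −ln(w)/k`. This classical distance is
  the Poisson approximation `D ≈ −ln(1−d)` and therefore overestimates `d`
  by `~d²/2` — half an ANI point at 10% divergence — which is why it is not
  the default for quantitative use.

`j = 0` is reported as "below resolution" (`None`), never as 0% ANI;
clustering treats such pairs as unlinked. Accuracy experiments use
`s = 20000` because the sampling error of the bottom-s Jaccard must stay
well under the ±0.5-point band at 10% divergence (at `s = 5000` the
estimator's standard error alone is ~0.25 points there).

## Quality scoring and greedy clustering

`score = completeness − 4·contamination`, retention at `score ≥ 50`
(inclusive — a bin at exactly 50 passes). Clustering makes one greedy pass
in descending score (ties: longer genome, then id); each genome joins the
existing representative of highest ANI meeting the threshold (inclusive
`≥` by default; the strict variant is a flag) or founds a cluster.
Representative selection therefore never needs a second pass. A two-phase
pre-cluster/refine pipeline (as dRep runs at scale) is intentionally
collapsed into this single pass: at desk scale (tens of genomes) the
quadratic sketch comparisons are cheap and the contract — a partition whose
representatives maximize quality, refined as the threshold rises — is what
the tests pin down.

## The synthetic communities

The generator emulates the statistical structure the recruitment statistics
live on: i.i.d. genomes at a chosen GC, populations with specified
community fractions, clonal intra-population divergence δ (each read's
template is an independent draw from the population cloud: substitutions at
rate δ, then sequencing errors at rate ε, both always changing the base),
sister clades derived by substitution at `1 − ANI/100`, and one embedded
single-copy marker locus (default 4 kb) per genome whose reads stand in for
a filtered rpoB pool (clipped to the locus, so expected aligned bases equal
depth × locus length exactly). Read counts are multinomial with weights ∝
abundance × genome length, origins uniform, strands forward-only, no indels
— so the truth aligner is exact and percent identity is a Hamming count.

What this does **not** emulate: indels (and thus gapped-alignment identity),
quality-score-dependent and GC-biased errors, chimeric assembly artifacts,
homologous marker sequences (marker-read identification is truth-based, as
it would be after model-based filtering), and real aligner behaviour
(mapping ambiguity, soft-clipping). Passing recovery tests therefore shows
the *statistics* are implemented correctly, not that any particular mapper
configuration reproduces them on real data.

Defaults: read length 150 bp, error rate 0.001, δ = 0.004.

### Problem sizes and read length in the experiments

The recovery experiments in `magpop.validation` run at desk scale, chosen by
an a-priori power analysis rather than tuned to outcomes:

* **ANIr recovery** — one 100 kb population at 50× (10k × 500 bp reads).
  The base-weighted estimator's standard error at this depth is ~0.002
  points, far inside the ±0.1 band around 100·(1−δ−ε).
* **Cutoff detection** — two 200 kb populations at 50× each. Identity of an
  L-bp gapless read is quantized in steps of 100/L, so L must exceed 200 for
  0.5-point bins to be populated at all (at L = 150 empty lattice bins mimic
  coverage gaps). 500 bp reads make the binomial identity spread narrow
  enough that the inter-cluster gap bin expects ~0.6 reads against a
  threshold of ~3 reads — the gap is detected, and the single-population
  control's tail stays below threshold, with comfortable margins.
* **Abundance recovery** — five 100 kb populations, 80k × 150 bp reads,
  ~120× pooled marker depth; the dominant error is the small TAD80 bias on
  skewed Poisson depth at the 5% population (~6×), a few percent relative.
* **Dereplication** — ten 200 kb genomes in three groups (within-group
  divergence ≤ 0.0025 so pairwise ANI ≥ 99.5%; between groups independent
  genomes, far below MinHash resolution); accuracy pairs on a 300 kb genome
  at divergences 0.01–0.10.

All experiments derive their seeds from a single integer, so reruns are
bit-reproducible; the full set completes in well under a minute.

## Pipeline and provenance

`run_pipeline` composes exactly the public functions (the tests assert the
composition property) per (genome, sample) pair and writes one combined TSV.
Every simulate/pipeline run emits a `manifest.json` (tool version, config
snapshot, SHA-256 of each input, timestamps); stdout-only subcommands print
a single value and emit no manifest. Logs go to stderr, results to files or
stdout, never interleaved.

## Known limitations

* Alignment-based ANI (fastANI-style) is not implemented; MinHash ANI
  degrades below ~85% identity and is reported as below-resolution there.
* The cutoff detector assumes a histogram with one dominant peak; two
  near-equal peaks above the threshold are treated as one cluster until the
  gap between them dips below threshold.
* BedGraph round-trips are byte-identical only for files in this package's
  canonical formatting (integers written bare, floats via `repr`).
* The enrichment classifier reports fold changes without p-values; it is a
  readout, not a test.
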