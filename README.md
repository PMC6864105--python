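# magpop

Population-genomics statistics for metagenome-assembled genomes (MAGs):
read-recruitment plots, truncated average depth (TAD80), sequence-discrete
population cutoffs, read-based average nucleotide identity (ANIr),
single-copy-marker (rpoB) normalized relative abundance, prevalence and
size-fraction enrichment summaries, and MinHash-based genome dereplication —
plus a ground-truthed synthetic community generator to validate all of it.

## Who this is for

Microbial ecologists tracking natural populations through metagenome time
series. Once MAGs are assembled and binned, the recurring questions are: how
abundant is each population in each sample, how diverse is each population
internally, where does one population end and its sister clade begin, and
which of many re-assembled bins are the same organism? `magpop` implements
the standard read-recruitment answers to these questions as a tested library
and a `popg` command line.

## The statistics

**TAD80.** Per-base depths of a genome (all contigs concatenated, zeros
included) are sorted and the top and bottom 10% of positions discarded; the
mean of the central 80% is robust against conserved-region pile-ups and
contig-edge dropoffs:

    TAD_q(g) = mean( sorted depths of g, trimmed by (1-q)/2 per tail ),  q = 0.8

**Relative abundance.** The pooled depth of a universal single-copy gene
(rpoB) proxies the genome-equivalent depth of the whole community, so

    abundance(g) = TAD80(g) / depth(rpoB pool),    depth = aligned bases / mean gene length

with detection declared when abundance > 0.01% (strict).

**Sequence-discrete cutoff.** Reads recruited to a reference form a
high-identity peak; the histogram of recruited bases by percent identity
drops by ~3 orders of magnitude at the population boundary. `detect_cutoff`
scans from the peak toward lower identity and reports the lower edge of the
last bin holding at least `peak * 10^-drop_orders`, provided recruitment
resumes beyond the gap (a discrete sister cluster or background); a clean
unimodal histogram reports "no discontinuity".

**ANIr.** The aligned-base-weighted (or per-read) mean identity of reads
recruited above the cutoff — a proxy for intra-population diversity;
clonal populations sit around 99.2–99.8%.

**Dereplication.** Genome quality = completeness − 4 × contamination
(keep ≥ 50). Pairwise ANI is estimated from bottom-s MinHash sketches of
canonical 21-mers (Jaccard j, shared k-mer fraction w = 2j/(1+j), ANI =
100·w^(1/k); the classical Mash transform 100·(1 + ln(w)/k) is available as
an option). A single greedy pass in descending quality order clusters
genomes at an ANI threshold (95% or 99%), so representatives maximize
quality within their cluster by construction.

## Worked example

Simulate a five-population community with known proportions
(0.40/0.30/0.15/0.10/0.05, clonal divergence δ = 0.004, sequencing error
ε = 0.001) and recover the proportions through the full pipeline:

```python
from magpop import validation as val

df = val.abundance_recovery(seed=1)
print(df[["population", "true_proportion", "tad80", "estimated_proportion"]]
      .round(4).to_string(index=False))
print(f"pooled marker depth: {df.attrs['marker_depth']:.1f}x")
```

```
population  true_proportion   tad80  estimated_proportion
      pop1             0.40 47.4955                0.3918
      pop2             0.30 36.0050                0.2970
      pop3             0.15 18.2212                0.1503
      pop4             0.10 12.1519                0.1002
      pop5             0.05  5.8836                0.0485
pooled marker depth: 121.2x
```

Every population is recovered within a few percent relative error: the
TAD80/marker-depth quotient is an accurate community fraction. Diversity and
boundary statistics on the same machinery:

```python
out = val.anir_recovery(seed=1)          # clonal population at 50x depth
print(f"ANIr = {out.anir:.3f}%  (expected {out.expected}%)")
cut = val.cutoff_detection(seed=1).cutoff  # equal-depth sister at 92% ANI
print(f"cutoff = {cut.cutoff}%, discontinuity_found = {cut.discontinuity_found}")
```

```
ANIr = 99.497%  (expected 99.5%)
cutoff = 98.0%, discontinuity_found = True
```

ANIr lands within 0.005 points of the true read identity 100·(1−δ−ε), and
the detected boundary (98%) separates the in-population peak from the
92%-ANI sister clade across a >10³ coverage gap.

The same workflow is scriptable from the shell:

```sh
popg simulate --config community.yaml --seed 42 --outdir sim/
popg pipeline --config run.yaml --outdir results/
popg derep bins/*.fasta --quality-table quality.tsv --ani 95 --out clusters.tsv
```

Each run writes a `manifest.json` with version, config snapshot, input
checksums and timestamps.

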