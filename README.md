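# igc2n

Multi-sample discovery, genotyping and reference-bias correction of germline
copy-number variants (CNVs) from SNP-array log2-ratio data.

Most CNV callers segment one genome at a time and therefore struggle with
small variants covered by a handful of markers and with rare variants whose
per-sample evidence is weak. `igc2n` instead borrows strength **across
samples**: a variant present in even a few individuals of a large cohort
leaves a recurrent footprint at the same markers, and that recurrence — not
any single sample's signal — is what gets tested. A second, less obvious
problem of array data is also addressed head-on: log2 ratios are always
taken against a reference set, and whenever the reference itself contains
carriers the whole locus is displaced by an unknown offset (the *reference
model bias*), so a cluster sitting at −1 need not be one copy — it may be
two copies measured against a duplicated reference. `igc2n` estimates that
offset explicitly and returns integer copy numbers.

## Method

Let `IR_ij` be the log2 intensity ratio of sample `i = 1..N` at marker
`j = 1..M`. Three steps:

**1. Detection.** Dichotomize: `B_ij = 1{|IR_ij| > t}` for a threshold `t`.
The per-marker score `S_j = Σ_i B_ij` counts individuals beyond the
threshold. Under the no-CNV null, `S_j ~ Binomial(N, p0)` with
`p0 = Σ_j S_j / (M·N)`, the genome-wide average score per sample; an
alternative permutation null permutes each sample's marker vector and pools
the permuted scores genome-wide. Upper-tail p-values are converted to
Benjamini–Hochberg q-values, and maximal runs of markers with `q ≤ 0.10`
become candidate loci `[p_1, p_n]` — with no restriction on the number of
covering markers or the locus size, which is what lets sub-kb variants
through. X/Y markers are excluded.

**2. CN class detection.** Each locus is summarized to a per-sample median
and a one-dimensional Gaussian mixture is fitted by EM for k = 1..6
components — variance tied across components except at k ∈ {2, 3} where the
deletion class may legitimately be wider; the lowest-BIC model wins; a
non-converged winner is refitted as a Student-t mixture (df = 4);
overlapping class intervals reduce k. Because EM will not open a class for
two or three carriers, a recursive Grubbs outlier scan then promotes extreme
samples to rare classes (classes closer than any real copy transition are
merged back). The gaps between consecutive class medians — the *1-CN class
differences* — are recorded.

**3. Bias correction and integer calls.** On the log2 scale the transitions
0–1, 1–2, 2–3, 3–4 have characteristic gaps 2.0, 1.0, log2(3/2) ≈ 0.585 and
log2(4/3) ≈ 0.415. A four-component mixture over the pooled 1-CN differences
of the run classifies each locus's gaps; a greedy highest-probability
assignment (with column removal) pins each class ladder to integer copy
numbers. Two pieces of genetics arbitrate: a dominant extreme class with
median within 0.25 of zero is anchored at CN 2 (frequent one-sided
polymorphisms push the reference, and hence the data, the other way), and a
CN 0 labelling must survive an exact binomial test of the observed
homozygous-deletion count against its Hardy–Weinberg expectation `p²`. The
reference bias estimate is the median of the CN 2 class (or of the centering
class, minus its theoretical log2 position).

A mechanistic simulator (`igc2n.simulator`) generates cohorts from the same
signal model the method assumes — marker-specific hybridization × copy
number × noise, normalized against a reference-set average so the bias
arises mechanically — on a 5-size × 3-frequency × 3-type CNV grid (90 CNVs
per dataset), and `igc2n.evaluation` scores power, false-positive rate,
Mendelian trio discordance, 50%-overlap equality and cross-platform
validation.

## Worked example

```python
import numpy as np
from igc2n import IgC2NPipeline, SimConfig, simulate_dataset

cfg = SimConfig(n_samples=200, n_markers=8000, size_classes=("medium", "large"),
                frequencies=(0.05, 0.15), seed=7)
matrix, marker_map, truth = simulate_dataset(cfg)

pipe = IgC2NPipeline(marker_map, t=0.6, random_state=0).fit(matrix)
print(f"candidate loci: {len(pipe.loci_)}")
print(f"genotyped polymorphic loci: {len(pipe.genotyped_loci_)}")

g = pipe.genotyped_loci_[0]
counts = {int(k): int(v) for k, v in zip(*np.unique(g.cn_calls, return_counts=True))}
print(f"locus {g.locus.name()}: type={g.polymorphism_type}, "
      f"maf={g.maf:.3f}, bias={g.bias_estimate:+.3f}, CN counts={counts}")
```

Output:

```
candidate loci: 71
genotyped polymorphic loci: 64
locus 1:1749-50876: type=del-gain, maf=0.075, bias=-0.025, CN counts={1: 6, 2: 185, 3: 9}
```

The pipeline found 71 candidate loci in the 200-sample cohort, of which 64
are polymorphic after mixture fitting. The first locus is a mixed
deletion/gain polymorphism: 6 samples carry one copy, 9 carry three, and the
estimated reference bias of −0.025 log2 units says the diploid cluster sits
essentially at its theoretical zero. Comparing `cn_calls` against the
simulator's `truth` gives ~94% per-sample genotype accuracy on this cohort.

The estimators follow scikit-learn conventions (`get_params`/`set_params`,
fitted attributes with trailing underscores), so `CNVDetector` and friends
compose with sklearn tooling; `igc2n detect / genotype / simulate / evaluate`
expose the same steps on the command line for TSV/BED files.

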