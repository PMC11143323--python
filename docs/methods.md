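# Methods

`clonefate` implements the genomic side of a clonal-fidelity comparison
between multi-region primary tumors (non-small cell lung cancer in the
motivating setting) and patient-derived xenograft (PDX) models grown from
those regions. The inputs are the products of an upstream
variant-calling / copy-number / clustering pipeline — a clone tree of
mutation clusters per tumor, per-sample cancer cell fractions (phyloCCF)
per cluster, allele-specific copy-number segment tables, caller-style
variant evidence, and an engraftment outcome table. This note records the
models, the parameters that matter, and the numerical choices.

## Clone proportions

A sample's cancer cells are partitioned by their most specific mutation
cluster. Because a cluster's CCF is the sum of the proportions over its
subtree, the proportion of clone *v* is

    p(v) = CCF(v) − Σ_{c ∈ children(v)} CCF(c),

proportions over present clones sum to 1, and a leaf's proportion equals
its CCF. Real CCF estimates are noisy, so negative proportions with
magnitude up to a tolerance τ (default 0.05) are clipped to zero and the
vector renormalized; a violation beyond τ raises a pigeonhole error
naming the cluster. Exact inputs are unaffected by the clipping, which is
what the synthetic round-trip tests exploit (inversion to ≤1e−12).

## Presence, clonality, engraftment patterns

A cluster is *present* in a sample when its CCF reaches the detection
threshold (default 0.01) and *clonal* when it reaches the clonal
threshold (default 0.9) or carries a clonal flag from the upstream
clustering. Engraftment of a PDX sample is *monoclonal* when every
cluster shared with the primary tumor is clonal within the PDX, and
*polyclonal* when any PDX-subclonal cluster is also present in the
primary; PDX-private clusters never affect the call. At the tumor level,
one polyclonal PDX makes the tumor polyclonal, and all-monoclonal PDX
samples are monoclonal only if their shared-cluster sets coincide.

Engrafting clones are identified leaf-up on the shared clusters mapped to
the tree: the deepest shared cluster of each branch engrafts; while the
current cluster is PDX-subclonal the walk moves to the nearest shared
ancestor, which engrafts when its phyloCCF strictly exceeds the summed
phyloCCF of the active child branches; the first PDX-clonal cluster
anchors the branch, engrafts, and stops the walk. Two open readings were
resolved as package choices: (1) the clonal anchor always engrafts even
when its phyloCCF equals the branch sum (the branch-merge behavior forces
this reading); (2) the subclonal starting tip is included by default
(`include_subclonal_tip=False` reports only anchors and qualifying
ancestors). "Strictly greater" is evaluated with an epsilon of 1e−9:
in exact synthetic data a pass-through ancestor's CCF equals the branch
sum to within float error, and without the epsilon the tie would resolve
by rounding noise.

## Distance scores

Mutational distance between regions i and j: mean absolute CCF difference
over the mutations present in at least one of the two samples, excluding
truncal mutations; bounded in [0, 1], 0 for identical profiles, 1 when
all non-truncal mutations are private and clonal. Truncal mutations are
those of clusters clonal in every primary region (the upstream pipeline's
trunk). When the item set is empty the score is 0 with an explicit
warning rather than NaN — such pairs differ only in truncal events and
are maximally similar.

Copy-number distance: the two segmentations are intersected into minimal
common intervals (breakpoint union, intervals covered by both profiles
only); over intervals aberrant in at least one sample — gain/loss is
relative to each sample's own rounded ploidy, so a genome-doubled sample
is scored against 4 — the score is the length-weighted mean absolute
difference in total copy number, Σ l·|CN_i − CN_j| / Σ l. Truncal
copy-number alterations (aberrant with identical total CN in all primary
regions) are excluded.

To ask whether a model's bottleneck was dominated by mutational or
copy-number divergence, both per-model distances to the region of origin
are z-transformed across the cohort; models in the upper quartile of
z_mut − z_cn are classified mutation-dominant, lower quartile CN-dominant,
the rest intermediate. Zero variance in either metric yields all
intermediate with a warning.

## Copy-number metrics

All segment states derive from integer (or real-valued, for reversion)
allele copy numbers: gain/loss relative to round(ploidy); LOH = minor
allele 0; allelic imbalance (AI) = unequal alleles; major-allele ties
label A. Genome-wide fractions use the declared genome lengths:

- proportion aberrant: length of gained/lost segments over genome length;
  the subclonal variant counts only events not shared by all samples of
  the tumor in the same direction.
- SCNA ITH: heterogeneous-event length over any-event length at tumor
  level (0/0 → 0 with warning).
- proportion identical: fraction of jointly covered length with equal
  total CN.
- wFLOH: unweighted mean over autosomes of per-chromosome LOH length over
  full chromosome length; sex chromosomes excluded. Full chromosome
  length (not callable length) is the denominator — a configurable
  choice.
- MSAI: of the length with AI in both samples, the fraction favoring
  opposite parental alleles (phasing must be consistent between samples);
  the denominator is configurable to "either".
- LOH reversion: origin segments with >10 heterozygous SNPs and minor CN
  < 0.1 are eligible; within their PDX-covered extent, length where the
  PDX minor CN reaches 0.1 counts as reverted. Reversion flags outgrowth
  of a minor non-LOH population, since LOH is irreversible per cell.
- WGD: major allele ≥ 2 over at least 50% of the genome (inclusive).

## Cohort procedures

Downsampling asks what single-region sampling would have yielded: each of
5000 iterations draws one region per patient uniformly and counts
patients whose drawn region engrafted; lymphoproliferative (hCD45+)
outgrowths always count as failures. The per-iteration expectation is
Σ_i s_i/r_i, which the Monte-Carlo mean must match within sampling error.

The recurrence scan tiles each chromosome into 5-Mb bins (trailing
partial bins kept); a sample is gained/lost in a bin when any overlapping
segment is, so segment fragmentation cannot change bin calls. Bins with
total event count within [min_count, max_count] are tested with a
two-sided Fisher exact test (conventional definition: sum of
probabilities of tables no more probable than observed) and BH-corrected
across tested bins; other bins are reported untested with the reason.
The count bounds are configuration (defaults 5 and no upper bound; the
published analysis used 5 with histology-specific upper bounds 26/41
derived from a power analysis whose alternative hypothesis is not
restated here, so the bounds are inputs rather than derived).

`cohort_from_marginals` reconstructs an outcome table from printed
per-histology attempt/success counts: regions spread evenly over
patients, successes packed into exactly the stated number of engrafting
patients and spread evenly among them. All rate-type summaries are exact
functions of the marginals; the downsampling median additionally depends
on the within-patient success layout, which the marginals do not fix.

## Variant filters

SNVs pass when (VAF > 2% with VarScan2 somatic p ≤ 0.01 and a MuTect
call) or (VAF ≥ 5% VarScan2-only with p ≤ 0.01), plus depth ≥ 30,
≥ 10 supporting reads, germline support < 5 reads and germline VAF ≤ 1%.
Variants passing in one region of a patient are re-queried in sibling
regions and rescued there at VAF ≥ 1% (only the VAF gate is relaxed;
stricter rescue gates are configurable). Indels use somatic p ≤ 0.001,
depth ≥ 50, and no minimum supporting-read count. Discordant indel calls
at one locus across regions unify to the longest predicted indel with the
maximum of depth, supporting reads and VAF. Adjacent passed SNVs merge
into a dinucleotide record when a two-sided two-sample proportion score
test (no continuity correction, α = 0.05) cannot reject equal allele
frequencies; the merged record carries the pair means of coverage and
counts.

## Strain-SNP spike-in and artifact audit

Mouse reads surviving host-read deconvolution masquerade as recurrent
human somatic variants. Two defenses are implemented. The spike-in
builds a host-strain-adapted reference: from a strain SNP VCF only
homozygous-alt and non-reference heterozygous records are retained
(ref/alt heterozygous dropped — a het site matches the reference half the
time and substituting it would hurt more than help), and the first
alternate allele is substituted into the FASTA, byte-identical elsewhere
with the input's line wrapping preserved. The audit flags non-driver
variants private to PDX samples (absent from all primary regions of the
same patient) that recur in two or more tumors — recurrent passenger
mutations across unrelated tumors are far more likely residual host reads
than convergent evolution.

## Synthetic cohorts

The generator produces every input with the structure the analysis
assumes and records ground-truth labels. Defaults mirror the motivating
study's conditions: 44 patients, 3 regions each, histology mix
20/15/9 (LUAD/LUSC/other), region-level engraftment probabilities
0.244/0.321/0.432, lymphoproliferation probability 0.11 among failed
attempts, 8 clusters per tumor, symmetric Dirichlet (α = 1) clone
proportions with 0.3 per-region clone dropout, a two-clone (polyclonal)
bottleneck in one third of models, founder sampling weight ∝
proportion^w with w = 1 (w = 0 admits minor clones), ~400× depth for
binomial read counts, and a compact genome of 22 autosomes plus X at
100 Mb each with 4 segments per chromosome. These sizes keep full
recovery suites (500 trees / 500 bottlenecks / 200 LOH runs) under a
minute while preserving the combinatorics that matter (branching,
dropout, merges).

Copy-number events attach to random clones and are inherited by their
subtrees; an allele lost to zero can never be regained, and gains never
target a zero-copy allele, so LOH is irreversible along lineages by
construction. Sample profiles are rounded proportion-weighted mixtures of
clone states, matching the integer segment tables the real pipeline
emits; the unrounded clone states are kept as ground truth.

Recorded PDX ground truth (`true_pattern`, `expected_engrafting`) encodes
what the bottleneck construction implies *under the clonal threshold*: a
second founder contributing less than 1 − threshold of the graft is
definitionally invisible to the thresholded classification, and a founder
sitting above an effectively clonal descendant is invisible to the
leaf-up walk, which stops at the first clonal cluster. The raw founder
set is recorded separately (`drawn_clones`). Passage drift appends
PDX-private clusters carved out of a founder's proportion and can jitter
CCFs; ground-truth labels are exact only at zero jitter.

What the generator does not emulate: purity/ploidy estimation error,
segmentation noise and breakpoint uncertainty, CCF estimation error from
read sampling (regional CCFs are exact subtree sums), mouse reads at the
read level, and clustering errors in the input tree. Passing recovery
tests therefore demonstrate correctness of the analysis logic under its
stated assumptions, not robustness to upstream estimation error; the
clipping tolerance, detection and clonal thresholds are the knobs that
absorb such error on real data.

## Known limitations

- The distance scores are not metrics (item sets vary by pair) and are
  not claimed to be.
- `split_independent_tumors` follows the published procedure (complete-
  linkage clustering on VAF vectors, one recursion, ≤ 4 tumors); linkage
  and VAF scaling are exposed because the original tool's defaults are
  not restated.
- MSAI assumes haplotype-consistent A/B labels between samples; the
  package does not re-phase.
- Bin-test count bounds are inputs; the power computation behind the
  published upper bounds is not re-implemented.
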