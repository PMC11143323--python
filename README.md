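# clonefate

Clonal-fidelity analysis of patient-derived xenograft (PDX) models
against multi-region primary tumors.

PDX models are grown by engrafting fragments of a patient's tumor into
immunodeficient mice. Multi-region sequencing shows primary tumors are
mosaics of genomic subclones, so a central question for anyone using PDX
models is how faithfully a model represents the region — and the tumor —
it came from. `clonefate` takes the outputs of an upstream
variant-calling / copy-number / phylogeny pipeline (clone trees, cancer
cell fraction tables, allele-specific segment tables, variant evidence,
engraftment outcomes) and quantifies that fidelity:

- **Clone proportions** on the phylogeny: `p(v) = CCF(v) − Σ CCF(children)`,
  summing to 1 per sample.
- **Engraftment clonality**: a PDX is *monoclonal* when every mutation
  cluster shared with the primary tumor is clonal in the PDX, *polyclonal*
  when a shared cluster stays subclonal; a leaf-up walk over the tree
  identifies the engrafting clones themselves.
- **Divergence scores**: mutational distance
  `d = (1/M) Σ_m |CCF_i,m − CCF_j,m|` over non-truncal mutations, and a
  length-weighted copy-number distance `Σ l·|CN_i − CN_j| / Σ l` over
  aberrant breakpoint-union intervals; plus a z-score classification of
  which divergence dominates each model's bottleneck.
- **Allele-specific copy-number metrics**: proportion of the genome
  aberrant (clonal/subclonal), SCNA intratumor heterogeneity, proportion
  identical, wFLOH, mirrored subclonal allelic imbalance (MSAI),
  LOH-reversion fraction, and whole-genome-doubling detection.
- **Cohort procedures**: single-region downsampling of engraftment
  attempts, cohort accounting, and a 5-Mb-bin recurrent gain/loss scan
  (Fisher exact + FDR).
- **Sequence QC**: the multi-region somatic variant filter rules
  (dual-caller/VAF/depth/germline gates with cross-region rescue),
  indel harmonization, dinucleotide merging, a mouse-strain SNP spike-in
  that builds a host-adapted reference FASTA, and an audit for recurrent
  PDX-unique passenger mutations that betray residual mouse reads.
- **Synthetic cohorts**: a seeded generator for every input above with
  ground-truth labels, used throughout the test suite.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
from clonefate.types import CloneTree
from clonefate.clonal import compute_clone_proportions
from clonefate.engraftment import classify_sample_engraftment, identify_engrafting_clones
from clonefate.distances import mutational_distance

tree = CloneTree("T1", {"B": "A", "C": "A"})          # A -> {B, C}
region_ccfs = {"A": 1.0, "B": 0.5, "C": 0.3}
pdx_ccfs = {"A": 1.0, "B": 0.5, "C": 0.5}

props = compute_clone_proportions(tree, region_ccfs).proportions
print({c: round(p, 3) for c, p in sorted(props.items())})
print(classify_sample_engraftment(tree, {"A", "B", "C"}, pdx_ccfs))
print(sorted(identify_engrafting_clones(tree, {"A", "B", "C"}, pdx_ccfs)[0]))
print(mutational_distance(region_ccfs, pdx_ccfs, truncal={"A"}).value)
```

prints

```
{'A': 0.2, 'B': 0.5, 'C': 0.3}
polyclonal
['A', 'B', 'C']
0.1
```

The region is heterogeneous (clone A retains 20% of cells, B 50%, C
30%). The PDX keeps B and C subclonal, so the engraftment is polyclonal;
the leaf-up walk starts at the subclonal tips B and C, sums their branch
CCFs (0.5 + 0.5) at the shared parent A, which is clonal in the PDX and
anchors the engrafting set {A, B, C}. The mutational distance to the
region of origin is the mean |ΔCCF| over the two non-truncal clusters:
(0 + 0.2)/2 = 0.1.

The same stages are available as a CLI — `clonefate simulate` writes a
complete synthetic input set, and `clonefate proportions / engraftment /
distances / cn-metrics / downsample / bin-test / filter-variants /
spike-reference / audit` run the pipeline file-to-file:

```sh
clonefate --seed 5 simulate --outdir fixtures/
clonefate proportions --tree fixtures/tree.tsv --ccf fixtures/ccf.tsv --out proportions.tsv
```

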