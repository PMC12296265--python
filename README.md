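# dualtrace

Dual-ensemble brain mapping and network analysis for activity-dependent
tagging experiments.

Immediate early genes (IEGs) such as *Fos* and *Arc* are transcribed within
minutes of neuronal activity, so their protein products mark the ensemble of
neurons active during a recent experience. Activity-dependent tagging
systems permanently label one ensemble with a fluorescent reporter (e.g.
eYFP) and a later IEG stain (e.g. c-Fos) marks a second ensemble; cells
carrying both labels are the reactivated overlap — the candidate engram
population. Mapping both ensembles and their overlap across coronally
sectioned brains, region by region, turns a cell-counting experiment into a
brain-wide functional-connectivity study.

`dualtrace` implements that workflow end to end, for scientists who
segment confocal z-stacks of two markers and want regional statistics and
correlation networks out the other side:

* **3D segmentation** of the two staining morphologies — punctate nuclear
  labels (Fourier band-pass → rolling-ball background subtraction → 3D
  local-maxima seeding → spot growth) and somatic labels with
  dendritic/axonal processes (background subtraction → 3D Gaussian blur →
  top-percentile threshold → watershed), plus object-based colocalization
  thresholded by percent volume overlap relative to the second channel.
* **A slice → mouse → experiment data model** with thin-plate-spline
  registration to 2D atlas plates, per-hemisphere region exclusions,
  shoelace (Gauss's formula) region areas, volumes as aggregated area ×
  section thickness, and counts normalized to cells/mm³.
* **Network statistics**: pairwise Pearson correlations of regional
  densities with asymptotic t-test p-values, networks thresholded at
  |r| > r_min and p < α, degree / clustering / nodal efficiency /
  betweenness, threshold-sweep stability curves, permutation tests of
  group correlation differences (r_IS − r_CT against a label-shuffle null),
  two-sample Kolmogorov–Smirnov comparison of a region's correlation
  distribution, and two-community detection from the sign of the leading
  eigenvector of the modularity matrix B = A − k kᵀ/(2m).
* **Synthetic fixtures with ground truth** — dual-channel 3D phantoms,
  toy atlas plates, and multi-mouse count datasets with planted
  correlation structure — so the whole pipeline is testable without any
  imaging data.

## Worked example

Segment a synthetic dual-channel stack, identify co-labeled cells, then
test a planted group difference in regional co-activity:

```python
from dualtrace.fixtures import (PhantomSpec, make_dual_channel,
                                CountSimSpec, simulate_region_counts)
from dualtrace.segment3d import (segment_punctate, compute_pairwise_overlaps,
                                 threshold_coloc)
from dualtrace import networks

spec = PhantomSpec(n_cells=12, snr=10.0, seed=1)
ch1, ch2, truth = make_dual_channel(spec, overlap_fraction=0.5)
r1, r2 = segment_punctate(ch1), segment_punctate(ch2)
pairs = compute_pairwise_overlaps(r1.labels, r2.labels)
colabeled = threshold_coloc(pairs, min_percent=50.0)
print(f"channel 1: {len(r1)} cells, channel 2: {len(r2)} cells")
print(f"candidate overlaps: {len(pairs)}, co-labeled at >=50%: {len(colabeled)}")

sim = CountSimSpec(region_names=["ACA", "AI", "dDG", "BLA", "SNr"],
                   n_per_group=8,
                   planted_diffs={("ACA", "AI"): (0.9, -0.9)}, seed=11)
ct, shock, _ = simulate_region_counts(sim)
corr_ct = networks.pairwise_correlations(ct)
result = networks.permutation_correlation_diff(ct, shock,
                                               n_permutations=1000, seed=0)
d, p = result.pair("ACA", "AI")
print(f"r(ACA, AI) in CT: {corr_ct.r[0, 1]:+.3f}")
print(f"correlation difference d = r_IS - r_CT = {d:+.3f}, permutation p = {p:.4f}")
```

prints

```
channel 1: 12 cells, channel 2: 12 cells
candidate overlaps: 6, co-labeled at >=50%: 6
r(ACA, AI) in CT: +0.923
correlation difference d = r_IS - r_CT = -1.838, permutation p = 0.0010
```

All 12 planted cells per channel are recovered; the 6 designed overlaps
(half the channel-2 population was placed on channel-1 centers) survive the
50% volume-overlap threshold and nothing else does. The ACA–AI pair was
planted at r = +0.9 in the control group and −0.9 in the shock group; the
observed difference of −1.84 is more extreme than every one of 1000
label-shuffled differences, giving the minimum attainable p of
(0 + 1)/(1000 + 1) ≈ 0.001.

The same analysis runs from a single YAML config on the command line:

```bash
dualtrace run config.yaml        # tables/, figures/, logs/ in output_dir
dualtrace segment --channel punctate stack.tif objects.tsv
dualtrace coloc --min-percent 50 ch1.labels.npy ch2.labels.npy coloc.tsv
dualtrace permute --n 1000 --seed 1 counts_ct.csv counts_is.csv diff.csv
```

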