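# dsim

Differential association testing between two sample groups for paired
probe-by-sample omics matrices (for example copy number as the dependent
platform and gene expression as the covariate platform).

For each dependent probe the method:

1. collects a genomic window of covariate probes (whole chromosome arm, or a
   base-pair window around the probe);
2. removes the association shared by both groups: ridge regression of the
   probe on its window over **all** samples, with the penalty chosen by
   exact leave-one-out cross-validation, keeping the cross-validated
   residuals;
3. tests whether the residual association differs between the groups: a
   variance-component score test on the covariate-by-group interaction
   `M_jk = X_jk * c_j`, where `c` is the zero-sum group contrast
   (`c_j = n_G2/n` for group 1, `-n_G1/n` for group 2);
4. permutes the covariate matrix's sample labels `B` times — the **same**
   permutations for every probe, reusing the penalty and residuals — to
   build an `m x (B+1)` p-value matrix;
5. applies a permutation-based false-discovery-proportion adjustment
   (quantile-count bound over the permuted columns) yielding one adjusted
   value per probe; probes with `adjusted <= level` are selected.

A per-group comparator (each group tested separately with
Benjamini–Hochberg FDR control) and a simulation suite with known ground
truth are included.

## CLI

All inputs are tab-delimited text: matrices are `probe_id` + one column per
sample; annotations are `probe_id chromosome arm start end` (1-based
inclusive; pass `--bed` for 0-based half-open); groups are
`sample_id group` with group in {1, 2}.

```sh
# simulate a preset dataset with known truth
dsim simulate --preset S2 --seed 3 --out sim/

# full two-group analysis (base-pair windows of 1 Mb total width)
dsim run --y sim/Y.tsv --x sim/X.tsv \
    --ann-dep sim/annotation_dep.tsv --ann-cov sim/annotation_cov.tsv \
    --groups sim/groups.tsv --window-bp 1000000 \
    --B 1000 --seed 17 --level 0.01 --out results/

# compare the selection against the simulated truth
dsim evaluate --selected results/dsim_results.tsv --truth sim/truth.tsv

# per-group baseline analysis at 5% FDR
dsim pergroup --y sim/Y.tsv --x sim/X.tsv \
    --ann-dep sim/annotation_dep.tsv --ann-cov sim/annotation_cov.tsv \
    --groups sim/groups.tsv --window-bp 1000000 --fdr 0.05 --out pergroup/

# stability of one probe's adjusted value across ridge penalties
dsim lambda-sweep --y sim/Y.tsv --x sim/X.tsv \
    --ann-dep sim/annotation_dep.tsv --ann-cov sim/annotation_cov.tsv \
    --groups sim/groups.tsv --probe cn_0026 --window-bp 1000000 \
    --out sweep.tsv
```

Use `--window arm` (default) for arm-level windows instead of `--window-bp`.
`--recompute-residuals` refits the baseline residuals per permutation at the
stored penalty (slow path; the default reuses the observed residuals, which
is valid because permuting rows of X leaves X'X unchanged).

## Library use

```python
from dsim import (read_matrix, read_annotation, read_groups,
                  align_samples, build_windows, run_dsim_arrays)

y = read_matrix("Y.tsv", role="dependent")
x = read_matrix("X.tsv", role="covariate")
groups = read_groups("groups.tsv")
y, x, groups = align_samples(y, x, groups)
windows = build_windows(read_annotation("ann_dep.tsv"),
                        read_annotation("ann_cov.tsv"),
                        mode="bp_window", window_bp=2_000_000)
run = run_dsim_arrays(y, x, groups, windows, B=1000, seed=17, level=0.1)
print(run.table.head())
```
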