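# rpcatree

Robust low-rank recovery coupled with tree-structure learning for noisy
single-cell matrices.

Single-cell sequencing data is a cells × features matrix whose rows
come from a small number of underlying states — tumor subclones sharing
a genotype, or cells moving along a branching developmental trajectory —
observed through heavy, sparse corruption: sequencing errors that flip
genotype states and dropout events that leave entries missing entirely.
`rpcatree` recovers the clean signal, the states, and the tree relating
the states in one optimization, for SNV genotype matrices ({0,1,2}),
copy-number state matrices, expression matrices, and generic point
clouds with sharp outliers.  It is a library first (with narrative
scripts under `examples/`) and also ships a thin `rpcatree` command for
shell use.

## Model

Given the observed matrix `X` with observed-entry set `Φ`, the method
estimates a low-rank signal `A`, a sparse error `E`, K cluster centers
`C`, a row-stochastic soft assignment `R`, and a spanning-tree
adjacency `B` over the centers, by minimizing

```
‖A‖·  +  λ‖P_Φ(E)‖₁  +  (θ/2) Σ b_{kk'} ‖C_k − C_{k'}‖²
      +  γ Σ_{ik} r_{ik} ‖A_i − C_k‖²  +  γσ Σ_{ik} r_{ik} log r_{ik}
s.t.  A + E = X,   B a spanning tree,   R row-stochastic,
```

with `‖·‖·` the nuclear norm.  Robust PCA (the first two terms) strips
sparse gross errors and imputes missing entries; entropy-regularized
soft K-means (the last two) groups the recovered rows; the minimum
spanning tree over the centers (the middle term) is the inferred
lineage or trajectory, and its smoothness penalty is what absorbs sharp
outliers instead of growing branches toward them.  The solver is an
alternating-direction scheme with closed-form or proximal block
updates and adaptive hyper-parameters `λ, θ, γ, σ, K` derived from the
data dimensions and noise scale; `docs/methods.md` has the full
derivation, the optimization schedule, and every default with its
rationale.

## Worked example

`examples/subclone_recovery.py` simulates 1000 cells × 300 mutation
sites from five subclones (193/235/93/241/238 cells) on a random clone
tree, flips 30% of the observed genotype states, drops 20% of entries,
and runs the full pipeline:

```
observed matrix: (1000, 300), missing rate 0.20
subclones found: 5 (sizes [235, 241, 193, 238, 93])
ARI vs true clones      : 1.0000
genotype error rate     : 0.0042
dropout imputed correct : 0.9955
FP+FN output/input ratio: 0.0137
clone tree edges (root clone 2): [(1, 3), (0, 4), (2, 4), (1, 4)]
```

Every cell lands in its true clone (adjusted Rand index 1.0), the five
recovered clone genotypes reproduce the truth to 99.6% of entries with
98.6% of the corruption removed (output/input error ratio 0.014), and
the rooted clone tree matches the simulated lineage.  The other
examples show outlier expulsion on 2-D shapes
(`denoise_outliers.py`), branching-trajectory reconstruction
(`branching_trajectory.py`), and the plain decomposition
(`denoise_matrix.py`).

From the shell, the same pipeline is:

```bash
rpcatree simulate scsnv -o sim --seed 1
rpcatree fit sim/observed.csv --kind snv -o out --seed 1
rpcatree evaluate --recovered out/recovered_A.csv \
    --truth sim/truth_matrix.csv --observed sim/observed.csv
```

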