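# nmfkit

Nonnegative matrix factorization (NMF) for gene expression analysis — and
any other nonnegative feature × sample data — with the multi-run machinery
that makes NMF usable in practice: several published algorithms behind one
interface, deterministic and stochastic seeding, consensus clustering
across repeated runs, factorization-rank estimation, metagene-specific
feature selection, and pre-configured heatmaps.

## The method

NMF approximates a nonnegative matrix `X` (n features × p samples) as

    X ≈ W H,    W ≥ 0 (n × r),  H ≥ 0 (r × p),  r ≪ min(n, p)

by minimizing a loss `D(X, WH)` — squared Frobenius norm or generalized
Kullback–Leibler divergence.  Columns of `W` are *metagenes*: nonnegative
expression patterns whose mixtures (columns of `H`) reconstruct each
sample.  Because factors are nonnegative and typically sparse, samples
cluster by their dominant metagene and each metagene is characterized by a
small set of specific genes.

Implemented algorithms: multiplicative updates for the Frobenius (`lee`)
and KL (`brunet`) losses, non-smooth NMF (`nsnmf`, a smoothing matrix
`S(θ)` forcing sparser factors), NMF with a feature-wise offset (`offset`),
and sparse NMF via alternating nonnegativity-constrained least squares
(`snmfr`).  Seeding: `random`, deterministic `nndsvd`, `ica` (positive
parts of an ICA), or an explicit starting factorization.  Stopping:
fixed iteration count, connectivity-matrix invariance, or objective
stationarity.  Repeated runs yield a consensus matrix whose cophenetic
correlation measures cluster stability and drives rank selection.
See `docs/methods.md` for formulas, defaults and design notes.

## Worked example

```python
from nmfkit import (make_synthetic, multifit, quality_report, reports_table,
                    survey, select_rank_brunet, select_rank_frigyesi)

d = make_synthetic(rng_seed=0)          # 200 genes x 30 samples, 3 groups
mf = multifit(d.X, 3, method="brunet", nrun=20, master_seed=2)
print(reports_table([quality_report(d.X, mf.best)]).to_string(index=False))

s = survey(d.X, [2, 3, 4, 5], nrun=20, master_seed=2, randomized=True)
print(s.as_frame().to_string(index=False))
print("selected rank (cophenetic rule):", select_rank_brunet(s))
print("selected rank (randomized-RSS rule):", select_rank_frigyesi(s))
```

prints

```
method   seed metric  rank     evar  sparseness_W  sparseness_H  purity  entropy  niter  cpu_time_s
brunet random     KL     3 0.979012      0.385071      0.459819     1.0      0.0     50         NaN
 rank  cophenetic   rss_best  evar_best  rss_best_random  cophenetic_random
    2    0.980828 428.081655   0.798338      1028.791287           0.948689
    3    1.000000  44.561170   0.979008       974.211572           0.871190
    4    0.999373  43.149750   0.979673       922.691465           0.915490
    5    0.998492  41.952645   0.980237       872.473478           0.864175
selected rank (cophenetic rule): 3
selected rank (randomized-RSS rule): 3
```

The best-of-20 KL fit explains 97.9% of the variance and clusters all 30
samples into their true groups (purity 1.0, entropy 0.0).  The rank survey
shows a perfectly stable consensus at the true rank 3 (cophenetic = 1) and
a sharp RSS elbow there: beyond r = 3 the marginal RSS decrease (~1.4)
falls below the decrease on randomized data (~50), so both heuristics
select r = 3.

Metagene-specific features are selected by entropy-based scoring with a
median + 3·MAD threshold:

```python
from nmfkit import make_marker_matrix, select_features
W, planted = make_marker_matrix(n=1000, r=3, rng_seed=0)
sel = select_features(W)
# -> selects 306/1000 rows (threshold s = 0.0034): 100% of the planted
#    marker rows, 0.9% of the uniform background rows
```

The same workflows are available from the shell:

```sh
nmfkit simulate --n 200 --p 30 --rank 3 --seed 0 --out-dir data
nmfkit fit --input data/synthetic.gct --labels data/labels.tsv \
           --rank 3 --method brunet --nrun 20 --seed 2 --out-dir run
nmfkit survey --input data/synthetic.gct --ranks 2:5 --nrun 20 \
              --randomized --seed 2 --out-dir run
nmfkit features --input data/synthetic.gct --rank 3 --nrun 20 --out-dir run
```

`fit` writes `W.tsv`, `H.tsv`, `consensus.tsv`, `report.json` (config and
all RNG seeds, enabling bit-identical re-runs) and the coefficient, basis
and consensus heatmaps plus the residual-track plot; every plot also writes
the plotted data as a sidecar TSV.

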