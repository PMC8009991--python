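# tdcsgraph

Graph-theoretic analysis of resting-state functional brain networks around
cathodal transcranial direct current stimulation (ctDCS) in focal epilepsy
— from parcellated ROI time series to density-thresholded weighted
connectomes, paired pre/post statistics across a density sweep, and an SVM
model that predicts treatment response from network change rates.

**Who it is for.** Researchers analyzing pre/post-intervention fMRI cohorts
who need the full chain — augmentation, connectivity, proportional
thresholding, weighted graph measures with rewired-null small-worldness,
FDR-corrected paired testing, and leakage-aware nested-CV prediction — as
tested, reproducible code. A built-in synthetic-cohort generator with a
planted treatment effect makes every stage testable without patient data.

## The analysis

A subject *responds* to ctDCS when the 4-week follow-up seizure count is at
least 20% below baseline. Each 230-timepoint scan (TR = 2 s) is cropped
into five overlapping windows (T = 90, stride 35); per window, Pearson
correlations between the 90 region-averaged signals are Fisher-transformed
(z = atanh r) and thresholded at densities d = 0.17…0.46 (step 0.01),
keeping the round(d·N(N−1)/2) strongest edges so all graphs share node and
edge counts. On each weighted graph (edge length 1/w for path measures):

| measure | definition |
| --- | --- |
| K_i | weighted degree, Σ_j w_ij |
| C_i, C_net | Onnela clustering (geometric-mean triangles, max-normalized weights); network mean |
| L_i, L_net | nodal mean shortest path length; characteristic path length |
| E_net | global efficiency, mean 1/d_ij |
| E_i | global efficiency of the neighbor subgraph |
| σ | (C_net/C_R)/(L_net/L_R) vs. 100 degree-preserving rewired nulls |

Site measures (K, C, L, E at the stimulation electrodes) average nodal
values over the mapped parcellation regions. Per group (responders /
non-responders / sham), pre vs post is compared at every density with
normality-gated paired tests and Benjamini–Hochberg FDR. Change rates of
C_net, L_net, E_net and site L at one density feed a maximal-information-
coefficient ranking, sequential forward selection, and an RBF-SVM evaluated
by nested cross-validation (group-aware folds by default, so windows of one
subject never straddle a split).

## Worked example

A downscaled synthetic cohort (20 regions, 12 active / 4 true responders /
8 sham, planted post-stimulation effect of 0.4 on within-module coupling):

```python
import json
import pandas as pd
from tdcsgraph.pipeline import RunConfig, run_pipeline
from tdcsgraph.synthetic_data import CohortConfig

config = RunConfig(
    out_dir="run",
    cohort=CohortConfig(
        n_regions=20, n_timepoints=230, n_active=12, n_sham=8,
        n_responders=4, block_sizes=(5, 5, 5, 5), rho_between=0.2, seed=11,
    ),
    d_min=0.38, d_max=0.44, step=0.02, feature_density=0.40,
    n_nulls=10, seed=11, outer_k=3, inner_k=3,
)
run_dir = run_pipeline(config)

stats = pd.read_csv(run_dir / "stats.csv")
print(stats[stats.significant_05].groupby(["group", "measure"]).size())
report = json.loads((run_dir / "prediction.json").read_text())
print(f"ACC {report['acc_mean']:.3f}  SN {report['sn_mean']:.3f}  "
      f"SP {report['sp_mean']:.3f}  AUC {report['pooled_auc']:.3f}")
```

Output (seed 11):

```
group                measure
active_nonresponder  K          4
active_responder     C_net      4
                     E_local    4
                     E_net      4
                     L_net      4
                     sigma      4
sham                 K          4
                     L_local    4
ACC 0.827  SN 0.715  SP 0.952  AUC 0.762
```

Reading this: the responder group shows the planted reorganization —
clustering (C_net) and efficiency (E_net, E_local) fall and path length
(L_net) rises significantly after stimulation at all four densities —
while no such pattern appears in non-responders or sham (the scattered K
and site-L flags in the control groups illustrate the anticonservatism of
sample-level pairing with overlapping windows; see `docs/methods.md`, and
use `subject_level_stats=True` for calibrated tests). The classifier
predicts response from the change rates well above chance (AUC 0.76).

The same run is available stage-by-stage from the shell:

```bash
tdcsgraph all --config config.yaml --out run --seed 11
tdcsgraph validate run/cohort
```

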