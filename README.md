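# mvbdecode

Single-trial decoding of rapid event-related fMRI by multivariate
Bayesian model comparison.

## The problem

In a rapid event-related design, stimuli appear every few seconds with
jittered fixation, so the slow hemodynamic response (peaking ~6 s after
an event) to each trial is contaminated by its neighbours. Given many
trials with *known* class labels and one or a few trials whose label is
*unknown* — the situation of, e.g., individualized memory-retrieval
testing where most stimuli come from a controlled simulation task —
the goal is to infer the unknown labels from the voxel time series.
Spatial patterns at single time points are unusable here; the temporal
model must carry the information.

## The method

The decoder reverses the usual GLM direction. A label hypothesis for the
unknown trials fixes a design matrix `X` (one HRF-convolved regressor
per class); the contrast `c = (+1, -1)` turns it into a target variable,
and after removing confounds `G` with the residual-forming matrix
`R = orth(I − GG⁻)ᵗ`, the target is regressed on the data:

    v = RXc = Lη + ζ,   L = RYU,   ζ ~ N(0, exp(λ_ς) RVRᵀ)
    β = Uη,  η ~ N(0, Σ_η),   Σ_η = Σ_k exp(λ_k) I⁽ᵏ⁾      (U = I)

The diagonal indicator components `I⁽ᵏ⁾` (nested subsets of voxels,
ranked by relevance) implement a sparse empirical prior on the voxel
weights: many voxels get near-zero prior variance, a few get large. Only
the hyperparameters λ are estimated, by maximizing the Laplace free
energy

    F = −½[vᵀΣ(λ)⁻¹v + ln|Σ(λ)| + w ln 2π]
        −½[(λ−π)ᵀΠ(λ−π) − ln|ΠΣ_λ|],     Σ(λ) = Σ_k exp(λ_k) Q_k

which also approximates the log model evidence. Classification of the
unknown trial is Bayesian model comparison: invert the model once with
the targets labeled A (`X_A`) and once labeled B (`X_B`), and pick the
label with the higher F.

The package also implements the baselines this approach is compared
against — a one-model MVB variant (targets omitted, correlation of the
weighted data projection with each hypothesis regressor), a GLM
T-weighted correlation classifier, and a linear SVM on trial-wise
("least-squares separate") betas with recursive feature elimination —
plus feature-mask construction from T maps (p < 0.001 uncorrected,
35-voxel clusters, union and contrast masks, overlap rate),
leave-one-out and multi-trial evaluation protocols with longest-ISI
reference selection, ISI/free-energy correlation analysis, and a fully
seeded synthetic BOLD simulator so every stage is testable without any
data download.

## Worked example

```python
from mvbdecode import (SimConfig, simulate_dataset, classify_two_model,
                       loo_crossval, isi_free_energy_analysis,
                       default_confounds, ar1_covariance)

cfg = SimConfig(n_voxels=48, n_trials_per_class=12, seed=7)
trials, bold, truth = simulate_dataset(cfg)

conf = default_confounds(bold.n_scans, bold.TR)
noise = ar1_covariance(bold.n_scans, 0.2)
res = classify_two_model(trials.with_targets([5]), bold, conf, noise)
print(f"trial 5: true={trials.labels[5]} predicted={res.predicted}")
print("evidence:", res.evidence, "margin", res.margin)

rep = loo_crossval(trials, bold, "mvb2")
print(f"LOO accuracy (mvb2): {rep.accuracy:.3f} over {rep.n_trials} trials")
records, stats = isi_free_energy_analysis(rep, trials)
print(f"free energy vs POST-ISI: r={stats['r_post']:.3f}")
```

prints

```
trial 5: true=B predicted=B
evidence: {'A': -91.88, 'B': -60.16} margin 31.73
LOO accuracy (mvb2): 1.000 over 24 trials
free energy vs POST-ISI: r=0.047
```

Trial 5's data are explained far better by the model that assigns it to
class B (free energy −60.2 vs −91.9; the margin of 31.7 log-evidence
units is decisive). Leave-one-out over all 24 trials classifies every
trial correctly at this signal-to-noise ratio, and trials followed by a
longer silent interval (POST-ISI) tend to carry stronger evidence
(weakly here, at 24 trials) — overlap from the *next* trial is what
hurts most.

There is also a CLI for shell pipelines over NIfTI/TSV inputs:

```sh
mvbdecode simulate --seed 3 --out-dir run/
mvbdecode crossval --method mvb2 --events run/events.tsv \
    --bold run/bold.nii.gz --mask run/mask.nii.gz --out run/cv.json
mvbdecode decode --method mvb2 --events my_events.tsv \
    --bold bold.nii.gz --mask mask.nii.gz --out decode.json
```

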