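# foxgate

Automatic gating and classification of FOXP3⁺ regulatory-T-cell
subpopulations from six-channel flow cytometry, for computational
immunologists and cytometry analysts who want a reproducible alternative
to manual gating.

## The problem and the method

CD4⁺FOXP3⁺ T cells split into three functionally distinct subsets —
CD45RO⁺FOXP3^high **effector Tregs**, CD45RO⁻FOXP3^low **naive Tregs**
and CD45RO⁺FOXP3^low **non-Tregs** — but FOXP3 is measured by
intranuclear staining with a continuous, high-background distribution,
so hand-drawn gates are subjective and hard to reproduce. `foxgate`
implements a three-step clustering pipeline (the *HKK* method) over the
channels (FSC, SSC, CD4, CD45RO, CD25, FOXP3):

1. **CD4⁺ identification** — a subspace-constrained Gaussian mixture
   (HDDC) with k = 3 on (FSC, SSC, CD4); per-cluster covariance
   Σ_k = Q_k diag(a_k1…a_kd_k, b_k…b_k) Q_kᵀ, fitted by EM; the cluster
   with the highest CD4 centroid is kept.
2. **FOXP3⁺ identification** — 1-D k-means with k = 3 on FOXP3 within
   the CD4⁺ cluster; highest-FOXP3 centroid wins.
3. **Subclassification** — k-means with k = 3 on (CD45RO, CD25, FOXP3);
   the highest-FOXP3 centroid is effector-Treg-like, the lowest-CD45RO
   centroid of the rest is naive-Treg-like, the last is non-Treg-like.

Preprocessing removes instrument-boundary pile-up events with
dialect-specific thresholds (analog/FCS 2.0 vs digital/FCS 3.x),
log₁₀-transforms fluorescence and standardizes every channel per sample.
Competing variants (HH, one-step-H, HKH), a manual-gating emulator with
the <0.2 % FOXP3-high calibration rule, a resampling evaluation
framework, and Mann–Whitney–Wilcoxon / Kruskal–Wallis cohort statistics
with Bonferroni adjustment are included, together with a synthetic
cytometry generator with ground-truth labels that makes the whole chain
testable without patient data.

## Worked example

```bash
foxgate simulate --n-events 20000 --seed 1 --out sample.csv
foxgate run --input sample.csv --method HKK --seed 7 --out result.csv
```

The second command prints the per-subpopulation percentages of CD4⁺
(and writes per-event labels plus a JSON summary):

```json
{
  "effector_treg_like": 6.74,
  "naive_treg_like": 4.55,
  "non_treg_like": 4.83,
  "foxp3_total": 16.12
}
```

The simulated sample was generated with mixture weights putting the
effector/naive/non-Treg populations at 6.5 %, 4.5 % and 5.1 % of CD4⁺
events, so the automatic pipeline recovers each subpopulation to within
a few tenths of a percentage point. The same library calls are available in
Python:

```python
import foxgate as fg
table, truth = fg.generate_sample(fg.default_sample_spec(seed=1))
result = fg.run_pipeline(table, fg.hkk_config(seed=7))
print(result.fractions)
```

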