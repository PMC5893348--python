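# regiodist

Regional intensity-distribution distances for characterizing
neurodegeneration in brain MR cohorts.

## The problem

Neurodegenerative disease — Alzheimer's disease in particular — does not
push every brain along one axis: individual patients drift away from the
healthy state in different directions, compromising different sets of
anatomical regions. `regiodist` quantifies that departure at the level
radiologists actually work: named atlas regions. For each subject, every
parcellated region is summarized by its histogram of gray levels (a proxy
for tissue composition / neuronal density), and regions are compared with a
true metric between probability distributions, the Earth Mover's Distance
(EMD). The control population supplies the baseline: its **medoid** — the
control subject with minimal summed distance to all other controls — becomes
the reference brain, and any subject is then described by the vector of
per-region EMDs to that reference. A boosted ensemble of one-region
threshold classifiers (RUSBoost, to absorb the usual control/patient
imbalance) separates groups and, as its main scientific output, ranks the
regions by how much they contribute — a clinically interpretable signature
of where the disease expresses itself.

The package is for neuroimaging researchers who already have skull-stripped
volumes registered to a common atlas space (registration itself is out of
scope) and want a reproducible, interpretable regional analysis; a synthetic
phantom generator makes the entire pipeline testable without any MR data.

## The core quantities

For two histograms *S* = {S₁,…,Sₙ} and *C* = {C₁,…,Cₘ} with equal integrals,
the EMD is the minimum-cost transport

&nbsp;&nbsp;min Σᵢⱼ |i−j| xᵢⱼ  s.t. Σⱼ xᵢⱼ ≤ Sᵢ, Σᵢ xᵢⱼ ≥ Cⱼ, xᵢⱼ ≥ 0,

normalized by the total moved mass — equivalently (1D, equal mass) the
Wasserstein-1 distance Σₖ |CDF_S(k) − CDF_C(k)| / mass, which is how the
production path computes it in O(n). Before comparison every histogram is
shifted so its center of mass sits on the central bin, which removes global
intensity offsets (scanner gain, background level).

The reference is medoid(A) = argmin_{x∈A} Σ_{y∈A} δ(x,y) over the control
group, with δ the sum of per-region EMDs. The feature matrix (subjects ×
regions of EMDs to the medoid) feeds RUSBoost: each round undersamples the
majority class, fits the best single-region threshold stump, and weights it
by α = ½ ln((1−ε)/ε) from its full-cohort weighted error ε. Region
importance is the α-weighted share of stumps per region, averaged over the
leave-one-out models; evaluation pools the out-of-fold scores into one ROC
(trapezoid AUC, interpolated equal error rate).

The bundled default parcellation has 113 regions (48 cortical per
hemisphere + 17 subcortical, Harvard–Oxford style names).

## Worked example

A fully synthetic run — 42 phantom subjects (30 controls, 12 patients),
20 regions of which regions 1–3 carry a planted tissue-composition shift:

```
$ regiodist simulate --preset small --out demo --seed 0
wrote 42 subjects to demo
$ regiodist extract --manifest demo/manifest.tsv --atlas demo/atlas.nii.gz \
      --labels demo/labels.tsv --out demo/extract
extracted 840 region histograms to demo/extract
$ regiodist featurize --extracted demo/extract --out demo/features
featurized 42 subjects x 20 regions
$ regiodist evaluate --features demo/features --out demo/eval --seed 0
AUC 0.964  EER 0.067
$ regiodist rank --evaluated demo/eval --top 5
   region  importance_percent
 region_1           80.752068
 region_3           14.900726
 region_2            4.209820
region_15            0.137386
 region_4            0.000000
```

Reading the output: leave-one-out classification of patients vs controls
reaches an area under the ROC curve of 0.964 with an equal error rate of
0.067 (6.7% false positives at the operating point where both error types
are equal), and the importance ranking concentrates on the three regions
that actually carry the planted effect — the remaining 17 regions share less
than 1%. Because redundant regions confirm rather than add information,
boosting splits relevance among them instead of crediting each fully, which
is why region 1 dominates here.

`regiodist train` fits one ensemble on a whole cohort and `regiodist apply`
scores a second cohort with it; `apply` refuses to run if the new features
were built under different histogram settings than the stored reference, so
cross-database transfer results stay valid.

## Layout

- `regiodist.volumes_io` — NIfTI volume/atlas loading, region sample
  extraction, Dice overlap QC
- `regiodist.histograms` — fixed-bin histograms, center-of-mass alignment
- `regiodist.emd` — closed-form and linear-program EMD
- `regiodist.population` — subject distances, medoid, feature matrices,
  group profiles
- `regiodist.classify` — stumps, RUSBoost, importance, LOOCV ROC
- `regiodist.synthetic` — phantom atlases and cohorts
- `regiodist.pipeline` / `regiodist.cli` — stage orchestration and the
  `regiodist` command

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
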