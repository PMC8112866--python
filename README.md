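# microdomain

Quantification of protein clustering in model-membrane fluorescence
imaging: single-molecule-calibrated cluster counting in TIRF fields,
Poisson modelling of clusters per liposome with exact two-sample rate
tests, lognormal cluster-size analysis, threshold-based colocalization
metrics, and FRAP immobile-fraction analysis. A synthetic-data generator
with full ground truth makes every stage testable end-to-end.

## Who this is for

Membrane biophysicists quantifying the clustering of a reconstituted
membrane protein — for example a small ER receptor that partitions into
cholesterol-dependent microdomains — in three standard assay geometries:

* **DSLB/TIRF fields**: a double supported lipid bilayer on glass imaged
  by total internal reflection fluorescence, where single fluorophores,
  small oligomers (trimers) and large clusters coexist;
* **GUVs**: giant unilamellar vesicles imaged at the equator as rings,
  scored for the number of protein clusters per liposome;
* **cellular colocalization / FRAP**: channel-overlap statistics and
  photobleaching-recovery kinetics.

## The statistics at the core

**Molecule counting.** A calibration field of mono-labelled single
fluorophores gives the mean integrated intensity *I₁* of one molecule.
Spots are segmented above a pixel threshold `background + k·A₁`, with
`A₁ = I₁ / (2πσ²)` the single-molecule peak amplitude implied by the PSF
width σ and `k = 5` by default; each spot's local-background-corrected
integrated intensity divided by *I₁* is its molecule count. Spots with
more than 10 molecules count as clusters, and the *clustered fraction* of
a field is Σ(cluster intensity) / Σ(total background-corrected protein
intensity).

**Clusters per liposome.** Counts *k*ᵢ over *n* liposomes are modelled as
Poisson(λ); the MLE is λ̂ = k̄ with an exact gamma 95% CI on the total
count and a χ² goodness-of-fit diagnostic. Two conditions (k₁, n₁) vs
(k₂, n₂) are compared with the exact conditional **C-test** — under H₀,
k₁ | (k₁+k₂ = K) ~ Binomial(K, n₁/(n₁+n₂)); the two-sided p sums all
outcomes no more probable than the observed one — and the unconditional
**E-test** (standardized rate difference with p by joint-Poisson lattice
summation under the pooled rate).

**Cluster sizes.** Molecule counts spanning tens to hundreds are fitted
as lognormal by MLE on log data, with a Kolmogorov–Smirnov diagnostic
(computed against the fitted parameters; the anti-conservatism of that
choice is carried in the result metadata). Frequency histograms use
half-open bins of width 2 molecules.

**Colocalization.** Mander's M₁ = Σᵢ∈B-mask Aᵢ / Σᵢ∈A-mask Aᵢ (and the
symmetric M₂), overlap-area fractions |A∩B|/|A|, and masked-intensity
fractions, with thresholds at *k*× the mean of the background-subtracted
channel (k = 1.5 for puncta channels).

**FRAP.** Double-normalized recovery traces are fitted with
y(t) = y_max·(1 − e^(−t/τ)); the plateau y_max is the mobile fraction and
1 − y_max (clipped to [0, 1]) the immobile fraction. Plateaus inside and
outside clusters are compared with a two-tailed t-test.

## Worked example

```python
from microdomain import simgen as sg
from microdomain.quant import calibrate_single_molecule, quantify_field
from microdomain.guv import analyze_guv_dataset
from microdomain.stats import PoissonRateModel, compare_poisson_rates

# calibrate the single-molecule intensity from a simulated singles field
calib_img, _ = sg.simulate_dslb_field(sg.FieldSimParams(
    seed=11, field_size_px=(512, 512), n_singles=200,
    single_intensity_cv=0.0, noise_model="none"))
calib = calibrate_single_molecule(calib_img, psf_sigma_px=1.3)
print(f"single-molecule intensity: {calib.single_intensity_mean:.1f} ADU")

# quantify a field with 60% of its molecules in 30-molecule clusters
field, truth = sg.simulate_dslb_field(sg.FieldSimParams(
    seed=12, n_singles=600, n_trimers=120, n_clusters=48,
    cluster_fixed_molecules=30))
print(quantify_field(field, calib).summary())

# count clusters per liposome in a simulated GUV dataset and fit Poisson
pairs, _ = sg.simulate_guv_set(sg.GUVSimParams(
    seed=13, n_liposomes=201, lambda_clusters=0.72))
_, summary = analyze_guv_dataset(pairs)
print(PoissonRateModel(summary.counts).fit().summary())

# compare two experimental conditions with the exact C-test
print(compare_poisson_rates(29, 194, 145, 201, method="ctest").summary())
```

prints

```
single-molecule intensity: 1000.1 ADU
Field quantification
--------------------
spots detected      : 47 (47 clusters)
background (ADU/px) : 108.26
total intensity     : 2323993.5
clustered intensity : 1459648.0
clustered fraction  : 0.6281
Poisson rate fit (clusters per liposome)
----------------------------------------
n liposomes     : 201
lambda_hat (MLE): 0.7065
95% CI (exact)  : [0.5951, 0.8327]
GOF chi2        : 1.026 (df=2), p=0.5988
Two-sample Poisson rate comparison (ctest)
-------------------------------------------------
group 1: k=29, exposure=194, rate=0.1495
group 2: k=145, exposure=201, rate=0.7214
statistic        : 29.0000
two-sided p      : 5.025e-19
```

The calibration recovers the generator's 1000 ADU single-molecule
intensity; the clustered fraction (0.628) sits within 0.05 of the 60%
ground truth; λ̂ = 0.71 recovers the generating rate 0.72 within its
sampling error; and the C-test finds the ~5-fold rate difference
overwhelmingly significant (p ≪ 0.001).

A command-line interface mirrors the library:

```bash
microdomain simulate guv --seed 3 --out guvdata/ --n-liposomes 50 --lambda-clusters 0.5
microdomain quantify guv guvdata/guv_field_*.tif --out guvrun
microdomain stats rates --k1 29 --n1 194 --k2 145 --n2 201
microdomain pipeline run --config examples/pipeline.yaml
```

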