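# dnasip

Analysis toolkit for DNA stable-isotope-probing (DNA-SIP) incubation
experiments, aimed at microbial ecologists tracing which community
members assimilate a ¹³C-labelled substrate (e.g. methanol or
methylamine) in seawater incubations.

In a DNA-SIP experiment, organisms that incorporate the labelled
substrate build ¹³C into their DNA, which raises its buoyant density so
it can be separated from unlabelled DNA on a CsCl density gradient.
`dnasip` implements the downstream inference chain:

* **Isotope mass balance.** δ¹³C of particulate organic carbon (POC) is
  converted to the ¹³C/¹²C atom ratio, R = (δ¹³C/1000 + 1)·R_VPDB with
  R_VPDB = 0.0112372, then to the ¹³C mass
  m(¹³C) = 13·m_POC·R / (13R + 12), giving the blank-corrected
  assimilation rate (m_sample − m_blank)/t and the ¹³C share of the POC
  pool.
* **Gradient fraction analysis.** DNA concentration profiles across a
  12-fraction gradient (1.687–1.770 g mL⁻¹, heavy first) are scanned
  for peaks, labelled vs blank profiles are scored for ¹³C/¹²C
  separation, fractions are split into heavy/light groups by
  group-average clustering of their community fingerprints, and
  representative H and L fractions are chosen at the in-group DNA peaks.
* **Incubation-time choice.** Among timepoints with distinguishable
  ¹³C/¹²C peaks, the one maximising the H–L Bray-Curtis dissimilarity
  is selected (ties to the earliest, minimising cross-feeding).
* **Community statistics.** Equal-depth rarefaction, Bray-Curtis
  dissimilarity, Shannon diversity H′ = −Σ pᵢ ln pᵢ, UPGMA dendrograms,
  nonmetric multidimensional scaling (Kruskal stress-1) and one-way
  ANOSIM with permutation p-values.
* **Ecotype classification.** OTUs above a 1 % relative-abundance
  filter are classified from their H, L and in-situ abundances into
  type I (rapid, dominant incorporation; H-enriched ≥ 3-fold),
  type II (slow/minor incorporation; similar H and L) and type III
  (no incorporation; lowest in H).
* **Synthetic SIP simulator.** A forward model with planted ground
  truth — GC-dependent buoyant density ρ = 1.660 + 0.098·GC, a
  0.036 g mL⁻¹ full-label shift, two-band Gaussian fractionation,
  multinomial read sampling, a δ¹³C-POC series that exactly inverts the
  mass-balance equations, and in-silico T-RFLP (MspI + RsaI double
  digest of 5′-labelled amplicons).

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated experiment (100 taxa, 5 rapid + 10 slow incorporators,
20 000 reads per fraction):

```sh
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_isotope_rates.py
python analysis/03_gradient_selection.py --seed 1
python analysis/04_community_comparison.py --seed 1
python analysis/05_ecotype_classification.py --seed 1
```

Step 02 recovers the planted total assimilation rate from the simulated
δ¹³C-POC series:

```
sample  time_days  assimilation_rate_ug_l_d  percent_13c
   MOH        1.0                      50.0     7.679634
   MOH        2.0                      50.0    14.242064
   MOH        3.0                      50.0    19.914550
   MOH        4.0                      50.0    24.866626

planted total rate 50.000 ug/L/d; worst relative recovery error 2.84e-16
```

i.e. the δ¹³C → atom-ratio → ¹³C-mass chain inverts the forward model
exactly, and by day 4 roughly a quarter of the POC pool is supplemental
¹³C. Step 03 then picks the representative fractions and incubation
time:

```
day 1: separation +0.0018 g/mL, distinguishable=False, H=None (true 13C band at 4), L=None
day 2: separation +0.0041 g/mL, distinguishable=False, H=4 (true 13C band at 4), L=9, H-L dissimilarity=0.9188
day 3: separation +0.0078 g/mL, distinguishable=True, H=4 (true 13C band at 4), L=9, H-L dissimilarity=0.9335
day 4: separation +0.0128 g/mL, distinguishable=True, H=4 (true 13C band at 4), L=9, H-L dissimilarity=0.9329

chosen incubation time: 3.0 d
```

The ¹³C band sharpens over time; day 3 gives the largest heavy–light
contrast among the timepoints with clearly separated ¹³C/¹²C peaks, and
the selected H fraction (4) sits exactly on the planted ¹³C band. Step
05 classifies the OTUs and scores recovery of the planted types:

```
chosen timepoint: 3.0 d
36 OTUs passed the >1% filter; calls: {'I': 6, 'III': 27, 'II': 3}
type-I sensitivity among classified rapid taxa: 1.0
incorporation false-positive rate: 0.0
```

All five planted rapid incorporators are recovered as type I (one
additional slow incorporator had already crossed the enrichment
threshold by day 3) and no non-incorporator is called an incorporator.

The same pipeline is available as a CLI (`dnasip simulate | isotope |
fractions | select | compare | ecotype | all`) for running individual
stages on your own fraction CSVs and OTU tables; see `dnasip --help`
for the file formats.

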