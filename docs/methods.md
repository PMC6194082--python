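# Methods

## Isotope mass balance

The ¹³C content of the particulate organic carbon (POC) pool is
described by the atom ratio R = n(¹³C)/n(¹²C). Measured δ¹³C (‰ vs
VPDB) converts to R via R = (δ/1000 + 1)·R_ref with R_ref = 0.0112372.
Some sources label R_ref an "atomic percent"; 0.0112372 is the VPDB
¹³C/¹²C *atom ratio* and the algebra only closes when it is used as
such, so the package implements it as an atom ratio throughout. The
¹³C mass of a POC pool of mass m_POC follows from isotope masses 13 and
12: m(¹³C) = 13·m_POC·R/(13R + 12). The assimilation rate is the
blank-corrected difference (m_sample(¹³C) − m_blank(¹³C))/t, and the
¹³C share of the POC pool uses the same numerator divided by m_POC, so
percent × m_POC ≡ rate × t by construction. Rates are cumulative
(elapsed-time averages, t = days since substrate addition), not
interval rates between consecutive samplings. Negative blank-corrected
values are legal outputs accompanied by a warning — clamping them would
hide measurement noise from diagnostics.

Units: masses in µg C per litre of incubated seawater, time in days,
rates in µg L⁻¹ d⁻¹, δ in ‰. The I/O layer encodes these in the column
names (`m_poc_ug_per_l`, `time_days`, …).

## Forward model (synthetic experiment)

The simulator emulates a batch seawater incubation fed 100 µM of a
99 % ¹³C-labelled C1 substrate, with a >98 % ¹²C blank, fractionated on
a 12-fraction CsCl gradient spanning 1.687–1.770 g mL⁻¹ (fraction 1 =
heaviest, matching the usual tube-puncture order).

**Buoyant density.** Unlabelled DNA bands at ρ = 1.660 + 0.098·GC
(the standard linear CsCl relation); full ¹³C substitution adds
0.036 g mL⁻¹, scaled by the DNA's ¹³C atom fraction. Both coefficients
are configuration, not constants in code.

**Two-band fractionation.** At time t a taxon's DNA is a mixture of an
unlabelled band at ρ(GC, 0) and a labelled band at ρ(GC, 0.99) with
weights (1 − λ(t), λ(t)), where λ(t) = 1 − e^(−kt) is the labelled DNA
fraction. Band mass per fraction is the Gaussian integral
(σ = 0.005 g mL⁻¹) over the fraction's density interval. The two-band
mixture — rather than a single drifting band — is what produces the
one-to-two-peak profiles real gradients show. A 2 % share of every
taxon's DNA is spread uniformly over all fractions, standing in for the
diffusive smearing that leaves measurable DNA in every fraction of a
real gradient (and keeping every fraction sequencable). Fraction DNA
concentrations receive multiplicative lognormal noise (CV 5 %, mean 1).

**Labelling and growth kinetics.** Rapid incorporators use
k = 1.5 d⁻¹ (λ > 0.5 within one day), slow incorporators k = 0.2 d⁻¹
(λ crosses 0.5 near day 4), non-incorporators λ ≡ 0. Incorporators also
bloom on the substrate pulse (exponential growth at 0.8 d⁻¹ for rapid,
0.3 d⁻¹ for slow taxa, ×2.2 and ×1.3 per day respectively), while
non-incorporators hold their base biomass; this is the confinement
("bottle effect") bloom that makes labelled DNA visible against the
background in real incubations. Growth rates are per-taxon fields, so
scenarios with growing non-incorporators are expressible.

**Community.** Base abundances are lognormal (σ = 1.5), normalised;
incorporator types are planted on uniformly chosen taxa regardless of
abundance, so most incorporators are rare — the regime reported for
rapid C1 incorporators in oligotrophic seawater. GC content is drawn
from a clipped normal (mean 0.5, sd 0.03, bounds [0.2, 0.8]). The
narrow default spread keeps the community's unlabelled density band
(≈0.098·ΔGC ≈ 0.01 g mL⁻¹ full width) comparable to the band width,
which reproduces the observed regime of a single coherent light peak
plus a resolvable ¹³C peak; communities with wide GC spread smear the
light DNA across many fractions and single-fraction SIP logically
cannot attribute a band to a taxon in that regime.

**Reads.** Each sequenced fraction draws `depth` reads (default
20 000) multinomially in proportion to per-taxon DNA mass — no PCR
bias, chimeras or sequencing error (by design; those belong to
upstream read-QC pipelines, not to this analysis).

**δ¹³C-POC series.** Both treatments assimilate the same substrate
carbon; the labelled bottle builds it at the substrate's 0.99 ¹³C atom
fraction, the blank at natural abundance (δ¹³C = −22 ‰ background, a
typical marine POC value). The planted per-taxon rates are defined as
blank-corrected ¹³C rates, and δ values are emitted through exact atom
bookkeeping (n₁₃ = m₁₃/13, n₁₂ = (m_POC − m₁₃)/12, R = n₁₃/n₁₂), so the
mass-balance chain recovers the planted total exactly when measurement
noise is off. Optional Gaussian δ noise (a mass-spectrometer precision
of ±0.2 ‰ is typical) and lognormal POC-mass noise are available.

**In-silico T-RFLP.** The terminal restriction fragment of a
5′-labelled amplicon is the distance from the labelled base to the
first cut by any enzyme of the double digest (MspI C^CGG, RsaI GT^AC;
IUPAC codes in recognition sites are expanded). Lengths are 1-based
integers including the labelled base; ±1 nt bin merging is not applied.

## Gradient analysis choices

Peak detection is a plateau-aware local-maxima scan over non-failed
fractions with a prominence floor of 0.1 × the profile maximum; plateau
ties resolve to the heaviest fraction. These two rules make the
by-eye peak calls of gradient figures deterministic. ¹³C/¹²C profiles
count as "distinguishable" when the DNA-weighted mean density shifts by
≥0.010 g mL⁻¹ or the DNA share at densities at or above the grid median
grows by ≥0.15 — explicit, configurable surrogates for a visual
judgement that has no published numeric criterion.

Heavy/light fraction groups come from the two-group cut of a UPGMA
dendrogram over Bray-Curtis dissimilarities between fraction
communities (the fingerprinting route used on real gradients); the
group with greater mean density is "heavy". Representative H and L
fractions are the highest-concentration peaks of the labelled profile
inside each group, L falling back to the blank profile's peak; a failed
fraction is replaced by its nearest usable in-group neighbour, heavier
on ties. Timepoint selection maximises H–L dissimilarity among
timepoints with distinguishable peaks (and ANOSIM p < α where
replication permits a test — unreplicated single gradients simply skip
that gate), breaking ties toward the earliest time to limit
cross-feeding. A timepoint whose heavy group contains no detectable
peak is reported unusable rather than an error of the whole run.

## Community statistics

Rarefaction is sampling without replacement (multivariate
hypergeometric), so subsampled counts never exceed the originals and
rows sum exactly to the target depth; samples below depth are dropped
with a warning. Bray-Curtis is computed on relative abundances by
default (raw-count mode available). Shannon diversity uses natural log
by default (the mothur convention), base configurable, and is computed
after rarefaction by default. UPGMA sorts labels lexicographically
before linkage so equal-distance merges are deterministic; dendrograms
export to newick with branch lengths as height differences. NMDS is
SMACOF with monotone (isotonic) regression of configuration distances
on the dissimilarity rank order (primary approach to ties), reporting
Kruskal stress-1 from the best of 20 seeded random starts; stress is
non-increasing within a run, a property the tests exercise directly.
ANOSIM uses mid-ranks on ties, R = (r̄_between − r̄_within)/(M/2), and a
label-permutation p-value with the observed statistic included
(p = (1 + #{R* ≥ R})/(1 + n_perm)), 999 permutations by default.

## Ecotype classification

OTUs enter classification only if their relative abundance exceeds 1 %
(strict) in at least one of the representative H, L or in-situ
libraries, computed after equal-depth rarefaction. Rules apply in
order: **I** if H/max(L, in-situ, ε) ≥ F; **III** if H is strictly
lowest; **II** if H ≥ 0.1 % and H/L lies within (1/F, F); otherwise
unclassified. F = 3 and the 0.1 % presence floor are explicit package
choices — the qualitative definitions ("enriched", "similar",
"lowest") carry no published thresholds — and live in `EcotypeConfig`.
Ties between H and L/in-situ fall to unclassified rather than III, so
type III always means a real depletion. At the latest timepoint of a
series, type-II calls carry a cross-feeding caveat: slow primary
incorporation cannot be separated from secondary labelling via
incorporator metabolites after long incubations. Clade-level summaries
aggregate calls by taxonomy string with median abundances per role;
the three response types are the general model, while any particular
study's clades are dataset-specific groupings of them.

## Problem sizes and numerical notes

The shipped analysis and acceptance runs use 100 taxa (5 rapid +
10 slow), 12 fractions, 20 000 reads per fraction, 4 timepoints,
20 replicate seeded experiments, 50 random isotope scenarios, and 200
null simulations for ANOSIM calibration — sizes at which every
behaviour of interest is already stable and the whole suite runs in
seconds. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (per-stage seeds kept below 2³¹
and recorded in run manifests), making every artefact byte-reproducible
from its manifest. Gaussian bands truncated at the gradient edges lose
<1 % of mass for the default community (tested); degenerate inputs —
flat profiles, all-zero fractions, symmetric density ties, groups of
size one — raise informative errors rather than guessing.

## Known limitations

The simulator does not model PCR/sequencing error, rRNA copy number,
primer mismatch, gradient tube-to-tube density drift, or
isotope-induced G+C compositional effects. Passing the planted-truth
recovery tests shows the inference chain is correct under the stated
forward model; it does not certify performance on communities with wide
GC spread (where single-fraction SIP is inherently confounded), under
heavy cross-feeding, or with compositional artefacts of amplicon
sequencing. ANOSIM requires ≥2 members per group, so unreplicated
gradients rely on the density-separation gate alone.
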