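"""Synthetic DNA-SIP experiment generator.

Emulates a stable-isotope-probing incubation end to end with planted
ground truth: a taxon community with GC-dependent buoyant density,
progressive ¹³C labelling that shifts DNA into heavier CsCl fractions,
fractionation of the gradient into equal density intervals, multinomial
read sampling per fraction, a δ¹³C-POC time series consistent with the
planted assimilation rates, and in-silico T-RFLP of synthetic 16S
sequences.

The forward model is the exact algebraic inverse of the analysis chain
wherever the analysis is deterministic, so downstream modules can be
tested for parameter recovery.

Model
-----
Buoyant density of unlabelled DNA follows the standard linear CsCl
relation ρ = 1.660 + 0.098·GC (g mL⁻¹); full ¹³C substitution adds a
configurable shift (default 0.036 g mL⁻¹).  Each taxon's DNA is a
mixture of two Gaussian bands — an unlabelled band and a band at the
substrate's ¹³C atom fraction — weighted by the taxon's labelled DNA
fraction at the sampling time.  This two-band mixture reproduces the
one-to-two-peak profiles seen in real gradients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .isotope import (
    IsotopeConstants,
    IsotopeMeasurement,
    Treatment,
    mass_13c,
    ratio_to_delta,
    delta_to_ratio,
)

# Labelling kinetics λ(t) = 1 − exp(−k t): rapid incorporators pass 50 %
# labelled DNA within a one-day incubation, slow ones only by day ~4.
RAPID_LABEL_RATE = 1.5  # d⁻¹  → λ(1 d) ≈ 0.78
SLOW_LABEL_RATE = 0.2  # d⁻¹  → λ(1 d) ≈ 0.18, λ(4 d) ≈ 0.55

# Incorporators bloom on the 100 µM C1 substrate pulse while the rest of
# the community is carbon-limited (the "bottle effect" bloom seen in
# batch incubations); non-incorporators default to no net growth.
RAPID_GROWTH_RATE = 0.8  # d⁻¹  → ×2.2 by day 1, ×25 by day 4
SLOW_GROWTH_RATE = 0.3  # d⁻¹  → ×1.3 by day 1, ×3.3 by day 4

EcotypeTruth = Literal["rapid", "slow", "none"]


@dataclass
class TaxonProfile:
    """One simulated taxon with planted ground truth.

    ``label_rate`` parameterises the labelled-DNA fraction
    λ(t) = 1 − exp(−label_rate·t); it is 0 for non-incorporators.
    """

    taxon_id: str
    gc_fraction: float
    base_abundance: float
    true_type: EcotypeTruth = "none"
    label_rate: float = 0.0
    growth_rate: float = 0.0  # d⁻¹; biomass factor exp(growth_rate·t)
    seq_16s: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.base_abundance < 0:
            raise ValueError("base_abundance must be non-negative")
        if self.true_type == "none" and self.label_rate != 0:
            raise ValueError("non-incorporators must have label_rate = 0")

    def labeled_dna_fraction(self, t: float) -> float:
        """Fraction of this taxon's DNA isotopically labelled at time t (days)."""
        if t < 0:
            raise ValueError("t must be non-negative")
        return 1.0 - math.exp(-self.label_rate * t)

    def growth_factor(self, t: float) -> float:
        """Multiplicative biomass change by time t."""
        return math.exp(self.growth_rate * t)


@dataclass(frozen=True)
class GradientConfig:
    """CsCl gradient and fractionation parameters.

    Defaults mirror a 12-fraction gradient spanning 1.687–1.770 g mL⁻¹
    (heavy-first numbering), a 0.036 g mL⁻¹ full-label density shift,
    99 % ¹³C substrate purity, and 5 % multiplicative noise on fraction
    DNA concentrations.
    """

    n_fractions: int = 12
    density_heavy: float = 1.770
    density_light: float = 1.687
    band_sigma: float = 0.005
    full_label_shift: float = 0.036
    substrate_atom_fraction: float = 0.99
    dna_noise_cv: float = 0.05
    background_smear: float = 0.02
    bd_intercept: float = 1.660
    bd_gc_slope: float = 0.098
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_heavy <= self.density_light:
            raise ValueError("density_heavy must exceed density_light")
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if self.band_sigma <= 0 or self.full_label_shift <= 0:
            raise ValueError("band_sigma and full_label_shift must be positive")

    def fraction_edges(self) -> np.ndarray:
        """Density interval edges, heavy to light (length n_fractions + 1)."""
        return np.linspace(self.density_heavy, self.density_light, self.n_fractions + 1)

    def fraction_densities(self) -> np.ndarray:
        """Midpoint density of each fraction, fraction 1 (heaviest) first."""
        e = self.fraction_edges()
        return (e[:-1] + e[1:]) / 2.0


@dataclass(frozen=True)
class IncubationScenario:
    """One incubation experiment: substrate, timepoints and planted rates."""

    substrate: Literal["MOH", "MMA"] = "MOH"
    substrate_conc_um: float = 100.0
    timepoints: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    m_poc0: float = 600.0  # initial POC, µg C L⁻¹
    planted_rates: Sequence[float] = ()  # per-taxon ¹³C rate, µg L⁻¹ d⁻¹
    natural_delta13c: float = -22.0  # background δ¹³C of marine POC, ‰

    def __post_init__(self) -> None:
        ts = list(self.timepoints)
        if not ts or any(t <= 0 for t in ts):
            raise ValueError("timepoints must be positive")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timepoints must be strictly increasing")


def buoyant_density(
    gc_fraction: float,
    labeled_atom_fraction: float,
    config: GradientConfig | None = None,
):
    """Equilibrium CsCl buoyant density (g mL⁻¹) of DNA.

    Linear in GC content with an additive shift proportional to the ¹³C
    atom fraction of the DNA: ρ = 1.660 + 0.098·GC + f·Δρ_full.
    """
    cfg = config or GradientConfig()
    gc = np.asarray(gc_fraction, dtype=float)
    f = np.asarray(labeled_atom_fraction, dtype=float)
    if np.any((gc < 0) | (gc > 1)) or np.any((f < 0) | (f > 1)):
        raise ValueError("gc_fraction and labeled_atom_fraction must lie in [0, 1]")
    out = cfg.bd_intercept + cfg.bd_gc_slope * gc + f * cfg.full_label_shift
    return out.item() if out.ndim == 0 else out


def make_community(
    n_taxa: int,
    n_rapid: int,
    n_slow: int,
    seed: int,
    gc_mean: float = 0.5,
    gc_sd: float = 0.03,
    gc_bounds: tuple[float, float] = (0.2, 0.8),
    abundance_sigma: float = 1.5,
    with_sequences: bool = False,
    seq_length: int = 900,
) -> list[TaxonProfile]:
    """Draw a reproducible community with planted incorporator types.

    Relative abundances come from a long-tailed lognormal and are
    normalised to sum to 1.  Incorporator types are assigned to randomly
    chosen taxa irrespective of abundance, so rapid incorporators are
    often rare — as observed for type I taxa in oligotrophic seawater.
    GC content is drawn from a clipped normal; the default spread
    (sd 0.03) keeps the unlabelled community's density band width
    (≈0.098·ΔGC) comparable to the centrifugation band width, which is
    what produces the single light DNA peak plus a resolvable ¹³C peak
    seen in real gradients rather than an unstructured smear.
    Incorporators also carry growth rates: they bloom on the substrate
    pulse while non-incorporators stay at their base biomass.
    """
    if n_rapid < 0 or n_slow < 0 or n_taxa <= 0:
        raise ValueError("taxon counts must be non-negative (n_taxa > 0)")
    if n_rapid + n_slow > n_taxa:
        raise ValueError("n_rapid + n_slow must not exceed n_taxa")
    rng = np.random.default_rng(seed)
    abund = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_taxa)
    abund /= abund.sum()
    gc = np.clip(rng.normal(gc_mean, gc_sd, size=n_taxa), *gc_bounds)
    types: list[EcotypeTruth] = ["none"] * n_taxa
    chosen = rng.choice(n_taxa, size=n_rapid + n_slow, replace=False)
    for i in chosen[:n_rapid]:
        types[i] = "rapid"
    for i in chosen[n_rapid:]:
        types[i] = "slow"
    label_rates = {"rapid": RAPID_LABEL_RATE, "slow": SLOW_LABEL_RATE, "none": 0.0}
    growth_rates = {"rapid": RAPID_GROWTH_RATE, "slow": SLOW_GROWTH_RATE, "none": 0.0}
    taxa = []
    for i in range(n_taxa):
        seq = _random_16s(rng, seq_length, gc[i]) if with_sequences else None
        taxa.append(
            TaxonProfile(
                taxon_id=f"OTU{i + 1:04d}",
                gc_fraction=float(gc[i]),
                base_abundance=float(abund[i]),
                true_type=types[i],
                label_rate=label_rates[types[i]],
                growth_rate=growth_rates[types[i]],
                seq_16s=seq,
            )
        )
    return taxa


def _random_16s(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random nucleotide string with the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


def simulate_gradient(
    community: Sequence[TaxonProfile],
    t: float,
    treatment: Treatment | str,
    config: GradientConfig | None = None,
    total_dna: float = 1000.0,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple["pd.DataFrame", pd.DataFrame]:
    """Centrifuge the community and fractionate the gradient.

    Each taxon's DNA mass (``total_dna × abundance × growth``) splits
    between an unlabelled Gaussian band at ρ(GC, 0) and a labelled band
    at ρ(GC, substrate purity), weighted (1−λ(t), λ(t)); the mass landing
    in each fraction is the Gaussian integral over that fraction's
    density interval.  Blank incubations force λ = 0 (a ¹²C substrate
    adds no label).  A small ``background_smear`` share of every taxon's
    DNA spreads uniformly over the gradient, emulating the diffusive
    smearing that leaves DNA detectable in all fractions of a real
    gradient.

    Returns
    -------
    fractions : DataFrame
        One row per fraction: ``fraction`` (1 = heaviest), ``density_g_ml``,
        ``dna_conc`` (with multiplicative lognormal noise when ``noise``),
        ``failed`` (always False here).
    masses : DataFrame
        Noise-free per-taxon DNA mass per fraction (taxa × fractions,
        columns = fraction ids).
    """
    cfg = config or GradientConfig()
    treatment = Treatment(treatment)
    if t < 0:
        raise ValueError("t must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    edges = cfg.fraction_edges()  # heavy → light, decreasing
    lo, hi = edges[1:], edges[:-1]  # per-fraction density interval
    n_frac = cfg.n_fractions
    mass = np.zeros((len(community), n_frac))
    smear = cfg.background_smear
    for i, taxon in enumerate(community):
        lam = 0.0 if treatment is Treatment.BLANK else taxon.labeled_dna_fraction(t)
        m_tax = total_dna * taxon.base_abundance * taxon.growth_factor(t)
        for weight, atom_frac in (
            (1.0 - lam, 0.0),
            (lam, cfg.substrate_atom_fraction),
        ):
            if weight == 0.0:
                continue
            centre = buoyant_density(taxon.gc_fraction, atom_frac, cfg)
            band = norm.cdf(hi, centre, cfg.band_sigma) - norm.cdf(lo, centre, cfg.band_sigma)
            mass[i] += (1.0 - smear) * weight * m_tax * band
        mass[i] += smear * m_tax / n_frac
    conc = mass.sum(axis=0)
    if noise and cfg.dna_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.dna_noise_cv**2))
        conc = conc * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_frac)
    fractions = pd.DataFrame(
        {
            "fraction": np.arange(1, n_frac + 1),
            "density_g_ml": cfg.fraction_densities(),
            "dna_conc": conc,
            "failed": False,
        }
    )
    masses = pd.DataFrame(
        mass,
        index=[tx.taxon_id for tx in community],
        columns=np.arange(1, n_frac + 1),
    )
    return fractions, masses


def simulate_reads(
    masses: pd.DataFrame,
    depth: int,
    seed: int,
    fractions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sequence fractions by multinomial sampling of per-taxon DNA mass.

    Returns a samples × OTUs count table (rows ``F<id>``), each row
    summing exactly to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    cols = list(masses.columns) if fractions is None else list(fractions)
    rows = {}
    for f in cols:
        m = masses[f].to_numpy(dtype=float)
        total = m.sum()
        if total <= 0:
            raise ValueError(f"fraction {f}: no DNA mass to sequence")
        rows[f"F{f}"] = rng.multinomial(depth, m / total)
    return pd.DataFrame.from_dict(rows, orient="index", columns=masses.index)


def simulate_poc_timeseries(
    scenario: IncubationScenario,
    constants: IsotopeConstants | None = None,
    delta_sd: float = 0.0,
    poc_cv: float = 0.0,
    seed: int = 0,
) -> list[IsotopeMeasurement]:
    """Emit δ¹³C-POC measurements consistent with the planted rates.

    Both treatments assimilate the same substrate carbon; the labelled
    incubation builds it at the substrate's ¹³C atom fraction (0.99),
    the blank at natural abundance.  The planted per-taxon rates are the
    blank-corrected ¹³C assimilation rates, so the δ → R → mass → rate
    analysis chain recovers their sum exactly when noise is off.

    δ values are computed through atom counts (n₁₃ = m₁₃/13,
    n₁₂ = (m_POC − m₁₃)/12, R = n₁₃/n₁₂) — the exact inverse of the
    mass-balance equations.  Optional Gaussian noise on δ (‰, sd) and
    multiplicative noise on POC mass models measurement error.
    """
    c = constants or IsotopeConstants()
    rng = np.random.default_rng(seed)
    rho_total = float(np.sum(scenario.planted_rates)) if len(scenario.planted_rates) else 0.0

    r_nat = delta_to_ratio(scenario.natural_delta13c, c.r_vpdb)
    a_nat = r_nat / (1.0 + r_nat)  # natural ¹³C atom fraction
    a_lab = GradientConfig().substrate_atom_fraction

    def mass_frac_13(a: float) -> float:
        return 13.0 * a / (13.0 * a + 12.0 * (1.0 - a))

    dmf = mass_frac_13(a_lab) - mass_frac_13(a_nat)
    out: list[IsotopeMeasurement] = []
    for t in scenario.timepoints:
        # substrate carbon assimilated by time t (same for both bottles)
        s_t = rho_total * t / dmf
        m13_nat0 = mass_13c(scenario.m_poc0, r_nat)
        for treatment, a in ((Treatment.LABELED, a_lab), (Treatment.BLANK, a_nat)):
            m_poc = scenario.m_poc0 + s_t
            m13 = m13_nat0 + s_t * mass_frac_13(a)
            if m13 > m_poc:
                raise ValueError("planted rates imply more 13C than total POC")
            n13, n12 = m13 / 13.0, (m_poc - m13) / 12.0
            delta = ratio_to_delta(n13 / n12, c.r_vpdb)
            if delta_sd > 0:
                delta += rng.normal(0.0, delta_sd)
            if poc_cv > 0:
                m_poc *= rng.lognormal(-0.5 * math.log(1 + poc_cv**2), math.sqrt(math.log(1 + poc_cv**2)))
            out.append(
                IsotopeMeasurement(
                    delta13c_poc=float(delta),
                    m_poc=float(m_poc),
                    t=float(t),
                    treatment=treatment,
                    label=scenario.substrate,
                )
            )
    return out


def labeled_band_peak(
    community: Sequence[TaxonProfile],
    t: float,
    config: GradientConfig | None = None,
) -> int:
    """Ground-truth fraction id of the ¹³C-DNA concentration peak.

    Integrates only the labelled bands (weight λ(t) per taxon) over the
    fraction grid and returns the fraction holding the most labelled
    DNA; used to verify that the pipeline's chosen H fraction lands on
    the planted ¹³C band.
    """
    cfg = config or GradientConfig()
    edges = cfg.fraction_edges()
    lo, hi = edges[1:], edges[:-1]
    total = np.zeros(cfg.n_fractions)
    for taxon in community:
        lam = taxon.labeled_dna_fraction(t)
        if lam == 0.0:
            continue
        centre = buoyant_density(taxon.gc_fraction, cfg.substrate_atom_fraction, cfg)
        band = norm.cdf(hi, centre, cfg.band_sigma) - norm.cdf(lo, centre, cfg.band_sigma)
        total += lam * taxon.base_abundance * taxon.growth_factor(t) * band
    if total.sum() == 0:
        raise ValueError("community has no labelled DNA at this time")
    return int(np.argmax(total)) + 1


# ---------------------------------------------------------------------------
# In-silico T-RFLP

#: (recognition site, cut offset) for the double digest used on 16S
#: amplicons: MspI C^CGG and RsaI GT^AC.
DEFAULT_ENZYMES: tuple[tuple[str, int], ...] = (("CCGG", 1), ("GTAC", 2))

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _expand_iupac(site: str) -> list[str]:
    seqs = [""]
    for ch in site.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in recognition site {site!r}")
        seqs = [s + b for s in seqs for b in _IUPAC[ch]]
    return seqs


def insilico_trf(
    seq: str,
    enzymes: Sequence[tuple[str, int]] = DEFAULT_ENZYMES,
) -> int | str:
    """Terminal restriction fragment length of a 5′-labelled amplicon.

    The sequence is assumed to start at the labelled 5′ primer base.
    All enzymes digest together; the T-RF is the distance (nt, 1-based,
    including the labelled base) from the 5′ end to the first cut over
    all recognition sites.  Returns ``"uncut"`` if no enzyme cuts.
    """
    seq = seq.upper()
    if any(ch not in "ACGT" for ch in seq):
        bad = sorted({ch for ch in seq if ch not in "ACGT"})
        raise ValueError(f"sequence contains invalid characters {bad}")
    best: int | None = None
    for site, offset in enzymes:
        for concrete in _expand_iupac(site):
            start = seq.find(concrete)
            while start != -1:
                cut = start + offset  # length of 5' fragment in nt
                if cut > 0 and (best is None or cut < best):
                    best = cut
                start = seq.find(concrete, start + 1)
    return best if best is not None else "uncut"


def trflp_profile(
    community: Sequence[TaxonProfile],
    masses: pd.DataFrame,
    enzymes: Sequence[tuple[str, int]] = DEFAULT_ENZYMES,
) -> pd.DataFrame:
    """Per-fraction T-RF relative-abundance profile.

    Aggregates each fraction's per-taxon DNA mass by the taxon's T-RF
    length (taxa without sequences are skipped); columns are fractions,
    rows T-RF lengths (or "uncut"), values relative abundances.
    """
    trf_by_taxon = {}
    for taxon in community:
        if taxon.seq_16s is not None:
            trf_by_taxon[taxon.taxon_id] = insilico_trf(taxon.seq_16s, enzymes)
    if not trf_by_taxon:
        raise ValueError("no taxa carry 16S sequences")
    sub = masses.loc[list(trf_by_taxon)]
    grouped = sub.groupby([trf_by_taxon[t] for t in sub.index]).sum()
    return grouped / grouped.sum(axis=0)


# ---------------------------------------------------------------------------
# Experiment bundle and ground truth

@dataclass
class SipExperiment:
    """All artefacts of one simulated SIP incubation series."""

    community: list[TaxonProfile]
    config: GradientConfig
    scenario: IncubationScenario
    fraction_tables: pd.DataFrame = field(default_factory=pd.DataFrame)
    otu_tables: pd.DataFrame = field(default_factory=pd.DataFrame)
    measurements: list[IsotopeMeasurement] = field(default_factory=list)

    def ground_truth(self) -> dict:
        return {
            "taxa": {
                tx.taxon_id: {
                    "true_type": tx.true_type,
                    "gc_fraction": tx.gc_fraction,
                    "base_abundance": tx.base_abundance,
                    "label_rate": tx.label_rate,
                }
                for tx in self.community
            },
            "planted_rates": list(map(float, self.scenario.planted_rates)),
            "substrate": self.scenario.substrate,
            "timepoints": list(map(float, self.scenario.timepoints)),
        }

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth(), indent=1))


def simulate_experiment(
    seed: int,
    n_taxa: int = 100,
    n_rapid: int = 5,
    n_slow: int = 10,
    depth: int = 20_000,
    config: GradientConfig | None = None,
    scenario: IncubationScenario | None = None,
    noise: bool = True,
) -> tuple[SipExperiment, dict]:
    """Run the full forward model for every (timepoint, treatment).

    Returns the experiment bundle plus a dict of per-(t, treatment)
    ``(fractions, masses, reads)`` triples keyed ``(t, "labeled"|"blank")``.
    """
    cfg = config or GradientConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    community = make_community(n_taxa, n_rapid, n_slow, seed=int(kids[0].generate_state(1)[0] % 2**31))
    rho = 50.0  # total planted ¹³C rate, µg L⁻¹ d⁻¹, split over incorporators
    incorp = [tx for tx in community if tx.true_type != "none"]
    rates = np.zeros(n_taxa)
    if incorp:
        w = np.array([tx.base_abundance for tx in community])
        mask = np.array([tx.true_type != "none" for tx in community])
        rates[mask] = rho * w[mask] / w[mask].sum()
    scen = scenario or IncubationScenario(planted_rates=tuple(rates))
    grad_rng = np.random.default_rng(int(kids[1].generate_state(1)[0] % 2**31))
    read_seed = int(kids[2].generate_state(1)[0] % 2**31)
    runs = {}
    frames, otus = [], []
    for t in scen.timepoints:
        for trt in (Treatment.LABELED, Treatment.BLANK):
            fr, ms = simulate_gradient(
                community, t, trt, cfg, noise=noise, rng=grad_rng
            )
            reads = simulate_reads(ms, depth, seed=read_seed + int(t * 10) + (0 if trt is Treatment.LABELED else 1))
            runs[(t, trt.value)] = (fr, ms, reads)
            fr2 = fr.copy()
            fr2.insert(0, "tube_id", f"{scen.substrate}_{trt.value}_t{t:g}")
            fr2.insert(1, "treatment", trt.value)
            fr2.insert(2, "timepoint_days", t)
            frames.append(fr2)
            r2 = reads.copy()
            r2.insert(0, "sample", [f"{scen.substrate}_{trt.value}_t{t:g}_{i}" for i in reads.index])
            r2.insert(1, "role", "fraction")
            r2.insert(2, "treatment", trt.value)
            r2.insert(3, "timepoint_days", t)
            otus.append(r2)
    # in-situ (unincubated, unfractionated) community sample
    insitu_rng = np.random.default_rng(read_seed + 10_007)
    insitu_counts = insitu_rng.multinomial(
        depth, np.array([tx.base_abundance for tx in community])
    )
    insitu = pd.DataFrame(
        [insitu_counts], index=["insitu_0"], columns=[tx.taxon_id for tx in community]
    )
    insitu.insert(0, "sample", "insitu_0")
    insitu.insert(1, "role", "in-situ")
    insitu.insert(2, "treatment", "blank")
    insitu.insert(3, "timepoint_days", 0.0)
    otus.append(insitu)
    noise_seed = int(kids[3].generate_state(1)[0] % 2**31)
    measurements = simulate_poc_timeseries(scen, seed=noise_seed)
    exp = SipExperiment(
        community=list(community),
        config=cfg,
        scenario=scen,
        fraction_tables=pd.concat(frames, ignore_index=True),
        otu_tables=pd.concat(otus, ignore_index=True),
        measurements=measurements,
    )
    return exp, runs


def write_fasta(community: Sequence[TaxonProfile], path: str | Path) -> None:
    """Write synthetic 16S sequences (taxa lacking sequences are skipped)."""
    with open(path, "w") as fh:
        for tx in community:
            if tx.seq_16s:
                fh.write(f">{tx.taxon_id}\n{tx.seq_16s}\n")
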