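"""Analysis of DNA distributions across CsCl density-gradient fractions.

Locates ¹³C- and ¹²C-DNA concentration peaks, scores the separation
between labelled and blank gradients, splits fractions into heavy/light
groups, picks the representative H and L fractions for sequencing, and
chooses the incubation time whose H/L contrast best reflects the active
substrate-incorporating community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotope import Treatment


@dataclass
class Fraction:
    fraction_id: int
    density: float
    dna_concentration: float
    failed: bool = False


@dataclass
class FractionSet:
    """One gradient run: ordered fractions, heaviest first.

    Densities must strictly decrease with fraction id (fraction 1 is the
    heaviest); a constructor argument in any other order is re-sorted
    with a warning.  Failed fractions carry no community profile but
    keep their density.
    """

    fractions: list[Fraction]
    treatment: Treatment = Treatment.LABELED
    timepoint: float = 0.0
    tube_id: str = ""

    def __post_init__(self) -> None:
        dens = [f.density for f in self.fractions]
        if any(b >= a for a, b in zip(dens, dens[1:])):
            warnings.warn(
                f"tube {self.tube_id or '?'}: densities not strictly decreasing; "
                "re-sorting heavy-first",
                stacklevel=2,
            )
            self.fractions = sorted(self.fractions, key=lambda f: -f.density)
        if any(f.dna_concentration < 0 for f in self.fractions):
            raise ValueError("DNA concentrations must be non-negative")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        treatment: Treatment | str = Treatment.LABELED,
        timepoint: float = 0.0,
        tube_id: str = "",
    ) -> "FractionSet":
        """Build from a frame with columns fraction, density_g_ml, dna_conc[, failed]."""
        failed = df["failed"] if "failed" in df else [False] * len(df)
        return cls(
            [
                Fraction(int(f), float(d), float(c), bool(x))
                for f, d, c, x in zip(df["fraction"], df["density_g_ml"], df["dna_conc"], failed)
            ],
            treatment=Treatment(treatment),
            timepoint=timepoint,
            tube_id=tube_id,
        )

    def usable(self) -> list[Fraction]:
        return [f for f in self.fractions if not f.failed]

    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    def by_id(self, fraction_id: int) -> Fraction:
        for f in self.fractions:
            if f.fraction_id == fraction_id:
                return f
        raise KeyError(fraction_id)


@dataclass
class PeakReport:
    """Peaks and the relative DNA profile of one gradient."""

    peak_fraction_ids: list[int]
    relative_profile: dict[int, float]
    weighted_mean_density: float


@dataclass
class TimepointRecord:
    t: float
    hl_dissimilarity: float
    peaks_distinguishable: bool
    anosim_r: float | None = None
    anosim_p: float | None = None


@dataclass
class TimepointDecision:
    records: list[TimepointRecord]
    chosen_t: float | None
    diagnostic: str = ""


def detect_peaks(fs: FractionSet, min_prominence: float = 0.1) -> PeakReport:
    """Locate DNA concentration peaks in a gradient profile.

    A peak is a non-failed fraction (or plateau of equal values) whose
    concentration strictly exceeds both flanking non-failed values and
    reaches at least ``min_prominence`` of the profile maximum.  Plateau
    ties resolve to the heaviest (lowest-id) fraction; plateaus touching
    the gradient edge count as peaks only if they exceed their single
    flank.  Peaks are returned sorted by concentration, descending.
    """
    usable = fs.usable()
    if len(usable) < 3:
        raise ValueError(f"need at least 3 non-failed fractions, got {len(usable)}")
    conc = np.array([f.dna_concentration for f in usable])
    ids = [f.fraction_id for f in usable]
    total = conc.sum()
    if total <= 0:
        raise ValueError("all usable fractions have zero DNA")
    rel = conc / total
    cmax = conc.max()
    peaks: list[tuple[float, int]] = []
    i, n = 0, len(conc)
    while i < n:
        j = i
        while j + 1 < n and conc[j + 1] == conc[i]:
            j += 1  # plateau [i, j]
        left_ok = i > 0 and conc[i - 1] < conc[i]
        right_ok = j < n - 1 and conc[j + 1] < conc[i]
        at_left_edge, at_right_edge = i == 0, j == n - 1
        is_peak = (
            (left_ok or at_left_edge)
            and (right_ok or at_right_edge)
            and not (at_left_edge and at_right_edge)  # flat profile
            and conc[i] >= min_prominence * cmax
            and conc[i] > 0
        )
        if is_peak:
            peaks.append((conc[i], ids[i]))  # heaviest fraction of plateau
        i = j + 1
    peaks.sort(key=lambda p: (-p[0], p[1]))
    dens = np.array([f.density for f in usable])
    return PeakReport(
        peak_fraction_ids=[pid for _, pid in peaks],
        relative_profile=dict(zip(ids, rel)),
        weighted_mean_density=float((dens * rel).sum()),
    )


def peak_separation(
    labeled: FractionSet,
    blank: FractionSet,
    min_shift: float = 0.010,
    min_heavy_share_gain: float = 0.15,
) -> tuple[float, bool]:
    """Score how far the labelled DNA profile is displaced toward heavy
    densities relative to the blank.

    ``separation_score`` is the difference in DNA-weighted mean buoyant
    density (g mL⁻¹).  The profiles count as distinguishable if the
    score reaches ``min_shift`` or the labelled gradient's DNA share at
    densities at or above the grid median grows by
    ``min_heavy_share_gain``.
    """
    d_lab, d_blk = labeled.densities(), blank.densities()
    if len(d_lab) != len(d_blk) or not np.allclose(d_lab, d_blk):
        raise ValueError("labeled and blank gradients must share the same fraction grid")
    rep_lab = detect_peaks(labeled)
    rep_blk = detect_peaks(blank)
    score = rep_lab.weighted_mean_density - rep_blk.weighted_mean_density

    median_density = float(np.median(d_lab))

    def heavy_share(fs: FractionSet, rep: PeakReport) -> float:
        return sum(
            share
            for fid, share in rep.relative_profile.items()
            if fs.by_id(fid).density >= median_density
        )

    gain = heavy_share(labeled, rep_lab) - heavy_share(blank, rep_blk)
    distinguishable = bool(score >= min_shift or gain >= min_heavy_share_gain)
    return float(score), distinguishable


def assign_heavy_light(
    fs: FractionSet, fraction_clusters: dict[int, int] | Sequence[set]
) -> tuple[set[int], set[int]]:
    """Label a two-group fraction clustering as heavy vs light.

    The group with the greater mean buoyant density is the heavy group.
    ``fraction_clusters`` may be a mapping fraction-id → group label or
    a sequence of two sets of fraction ids.
    """
    if isinstance(fraction_clusters, dict):
        groups: dict[int, set[int]] = {}
        for fid, g in fraction_clusters.items():
            groups.setdefault(g, set()).add(fid)
        clusters = list(groups.values())
    else:
        clusters = [set(c) for c in fraction_clusters]
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(clusters)}")
    usable_ids = {f.fraction_id for f in fs.usable()}
    covered = clusters[0] | clusters[1]
    if covered != usable_ids:
        raise ValueError(
            f"clustering must cover all non-failed fractions exactly; "
            f"got {sorted(covered)} vs {sorted(usable_ids)}"
        )
    means = [np.mean([fs.by_id(i).density for i in c]) for c in clusters]
    if np.isclose(means[0], means[1]):
        raise ValueError("degenerate clustering: equal mean densities")
    if means[0] >= means[1]:
        return clusters[0], clusters[1]
    return clusters[1], clusters[0]


def _nearest_usable(fs: FractionSet, fid: int, group: set[int]) -> int:
    """Nearest non-failed in-group fraction; ties go to the heavier (lower id)."""
    candidates = [f.fraction_id for f in fs.usable() if f.fraction_id in group]
    if not candidates:
        raise ValueError(f"no usable fraction in group {sorted(group)}")
    return min(candidates, key=lambda c: (abs(c - fid), c))


def select_representative_fractions(
    fs_labeled: FractionSet,
    fs_blank: FractionSet,
    heavy_group: set[int],
    light_group: set[int],
) -> tuple[int, int]:
    """Choose the representative H and L fractions for sequencing.

    H is the highest-concentration peak of the labelled gradient inside
    the heavy group; L the highest-concentration labelled peak inside
    the light group, falling back to the blank gradient's peak when the
    labelled profile has none there.  A failed selection is replaced by
    the nearest non-failed fraction in the same group (ties to the
    heavier fraction).
    """
    peaks_lab = detect_peaks(fs_labeled)
    peaks_blk = detect_peaks(fs_blank)

    def pick(group: set[int], role: str) -> int:
        for pid in peaks_lab.peak_fraction_ids:  # concentration-descending
            if pid in group:
                return pid
        if role == "L":
            for pid in peaks_blk.peak_fraction_ids:
                if pid in group:
                    return pid
        raise ValueError(
            f"no DNA peak inside the {role} group {sorted(group)}; "
            f"labelled peaks at {peaks_lab.peak_fraction_ids}, "
            f"blank peaks at {peaks_blk.peak_fraction_ids}"
        )

    h = pick(heavy_group, "H")
    l = pick(light_group, "L")
    if fs_labeled.by_id(h).failed:
        h = _nearest_usable(fs_labeled, h, heavy_group)
    if fs_labeled.by_id(l).failed:
        l = _nearest_usable(fs_labeled, l, light_group)
    return h, l


def select_timepoint(
    records: Iterable[TimepointRecord], alpha: float = 0.05
) -> TimepointDecision:
    """Choose the incubation time that best separates H from L.

    Eligible timepoints have distinguishable ¹³C/¹²C peaks and, where an
    ANOSIM p-value is available, p < alpha.  Among the eligible, the
    timepoint with the largest heavy–light Bray-Curtis dissimilarity
    wins; ties go to the earliest time to minimise cross-feeding.  If no
    timepoint is eligible the decision is empty with a diagnostic.
    """
    recs = sorted(records, key=lambda r: r.t)
    if not recs:
        raise ValueError("no timepoint records supplied")
    eligible = [
        r
        for r in recs
        if r.peaks_distinguishable and (r.anosim_p is None or r.anosim_p < alpha)
    ]
    if not eligible:
        return TimepointDecision(
            records=recs,
            chosen_t=None,
            diagnostic=(
                "no eligible timepoint: peaks indistinguishable or ANOSIM not "
                f"significant at alpha={alpha} for all of "
                f"{[r.t for r in recs]}"
            ),
        )
    best = max(eligible, key=lambda r: (r.hl_dissimilarity, -r.t))
    return TimepointDecision(records=recs, chosen_t=best.t)
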