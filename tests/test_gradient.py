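"""Peak detection, H/L grouping, representative fractions, timepoint choice."""

import numpy as np
import pytest

from dnasip.gradient import (
    Fraction,
    FractionSet,
    TimepointRecord,
    assign_heavy_light,
    detect_peaks,
    peak_separation,
    select_representative_fractions,
    select_timepoint,
)
from dnasip.isotope import Treatment
from dnasip.simulate import (
    GradientConfig,
    TaxonProfile,
    simulate_gradient,
)

GRID = GradientConfig().fraction_densities()


def make_fs(concs, failed=(), treatment=Treatment.LABELED, t=1.0):
    return FractionSet(
        [
            Fraction(i + 1, float(GRID[i]), float(c), (i + 1) in failed)
            for i, c in enumerate(concs)
        ],
        treatment=treatment,
        timepoint=t,
    )


def brute_force_peaks(concs, min_prominence=0.1):
    """Independent oracle: plateau-aware local-maxima scan."""
    peaks = []
    n = len(concs)
    cmax = max(concs)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and concs[j + 1] == concs[i]:
            j += 1
        left = concs[i - 1] if i > 0 else None
        right = concs[j + 1] if j < n - 1 else None
        interior_max = (left is None or left < concs[i]) and (right is None or right < concs[i])
        if (
            interior_max
            and not (left is None and right is None)
            and concs[i] >= min_prominence * cmax
            and concs[i] > 0
        ):
            peaks.append(i + 1)
        i = j + 1
    return sorted(peaks, key=lambda p: (-concs[p - 1], p))


class TestDetectPeaks:
    def test_two_peak_profile(self):
        concs = [1, 2, 10, 3, 2, 2, 2, 9, 2, 1, 1, 1]
        rep = detect_peaks(make_fs(concs))
        assert rep.peak_fraction_ids == brute_force_peaks(concs) == [3, 8]

    def test_single_gaussian_band_has_one_peak(self, clean_gradient_config):
        tx = [TaxonProfile("t1", 0.5, 1.0)]
        fr, _ = simulate_gradient(tx, 0.0, Treatment.BLANK, clean_gradient_config, noise=False)
        rep = detect_peaks(FractionSet.from_frame(fr))
        assert len(rep.peak_fraction_ids) == 1
        # mode fraction holds the band centre 1.709
        mode = rep.peak_fraction_ids[0]
        assert fr.set_index("fraction").loc[mode, "dna_conc"] == fr["dna_conc"].max()

    def test_flat_profile_has_no_peaks(self):
        rep = detect_peaks(make_fs([3.0] * 12))
        assert rep.peak_fraction_ids == []

    def test_plateau_resolves_to_heaviest(self):
        rep = detect_peaks(make_fs([1, 5, 5, 5, 1, 1, 1, 1, 1, 1, 1, 1]))
        assert rep.peak_fraction_ids == [2]

    def test_failed_fractions_are_skipped(self):
        concs = [1, 2, 10, 3, 2, 2, 2, 9, 2, 1, 1, 1]
        rep = detect_peaks(make_fs(concs, failed={3}))
        assert 3 not in rep.peak_fraction_ids
        assert 3 not in rep.relative_profile

    def test_relative_profile_sums_to_one(self):
        rep = detect_peaks(make_fs([1, 2, 10, 3, 2, 2, 2, 9, 2, 1, 1, 1], failed={5}))
        assert sum(rep.relative_profile.values()) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_usable_fractions(self):
        with pytest.raises(ValueError):
            detect_peaks(make_fs([1, 2, 3], failed={1}))

    def test_random_profiles_match_oracle(self, rng):
        for _ in range(50):
            concs = list(rng.integers(0, 8, size=12))
            if max(concs) == 0:
                continue
            assert detect_peaks(make_fs(concs)).peak_fraction_ids == brute_force_peaks(concs)


class TestPeakSeparation:
    def test_identical_profiles_not_distinguishable(self):
        fs = make_fs([1, 2, 10, 3, 2, 2, 2, 9, 2, 1, 1, 1])
        score, dist = peak_separation(fs, fs)
        assert score == 0.0 and dist is False

    def test_fully_labeled_taxon_shifts_mean(self, clean_gradient_config):
        cfg = clean_gradient_config
        taxa = [
            TaxonProfile("lab", 0.5, 0.5, "rapid", label_rate=50.0),
            TaxonProfile("bg", 0.5, 0.5),
        ]
        fr_l, _ = simulate_gradient(taxa, 4.0, Treatment.LABELED, cfg, noise=False)
        fr_b, _ = simulate_gradient(taxa, 4.0, Treatment.BLANK, cfg, noise=False)
        score, dist = peak_separation(
            FractionSet.from_frame(fr_l), FractionSet.from_frame(fr_b, Treatment.BLANK)
        )
        # half the DNA carries the full 0.0356 g/mL shift
        assert score == pytest.approx(0.5 * 0.99 * 0.036, abs=2e-3)
        assert dist is True

    def test_blank_replicates_rarely_distinguishable(self, community):
        # Monte Carlo under the 5 % concentration-noise model
        cfg = GradientConfig()
        hits = 0
        n = 100
        for s in range(n):
            rng1 = np.random.default_rng(1000 + s)
            rng2 = np.random.default_rng(2000 + s)
            fr1, _ = simulate_gradient(community, 1.0, Treatment.BLANK, cfg, rng=rng1)
            fr2, _ = simulate_gradient(community, 1.0, Treatment.BLANK, cfg, rng=rng2)
            _, dist = peak_separation(
                FractionSet.from_frame(fr1, Treatment.BLANK),
                FractionSet.from_frame(fr2, Treatment.BLANK),
            )
            hits += dist
        assert hits <= 5  # ≥95/100 not distinguishable

    def test_monotone_in_labeled_fraction(self, clean_gradient_config):
        cfg = clean_gradient_config
        scores = []
        for k in [0.0, 0.2, 0.8, 3.0]:
            taxa = [TaxonProfile("t", 0.5, 1.0, "rapid" if k else "none", label_rate=k)]
            fr_l, _ = simulate_gradient(taxa, 1.0, Treatment.LABELED, cfg, noise=False)
            fr_b, _ = simulate_gradient(taxa, 1.0, Treatment.BLANK, cfg, noise=False)
            s, _ = peak_separation(
                FractionSet.from_frame(fr_l), FractionSet.from_frame(fr_b, Treatment.BLANK)
            )
            scores.append(s)
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_mismatched_grids_rejected(self):
        fs1 = make_fs([1] * 12)
        fs2 = FractionSet([Fraction(1, 1.75, 1.0), Fraction(2, 1.70, 1.0), Fraction(3, 1.69, 1.0)])
        with pytest.raises(ValueError):
            peak_separation(fs1, fs2)


class TestAssignHeavyLight:
    def test_published_grouping(self):
        # heavy group = fractions 1–3 and 5 on the default grid
        fs = make_fs([1, 2, 10, 3, 2, 2, 2, 9, 2, 1, 1, 1], failed={4, 6, 7})
        heavy, light = assign_heavy_light(fs, [{1, 2, 3, 5}, {8, 9, 10, 11, 12}])
        assert heavy == {1, 2, 3, 5}

    def test_ordered_halves(self):
        fs = make_fs([1] * 12)
        heavy, light = assign_heavy_light(fs, [set(range(1, 7)), set(range(7, 13))])
        assert heavy == set(range(1, 7)) and light == set(range(7, 13))

    def test_wrong_group_count_rejected(self):
        fs = make_fs([1] * 12)
        with pytest.raises(ValueError):
            assign_heavy_light(fs, [set(range(1, 13))])

    def test_incomplete_cover_rejected(self):
        fs = make_fs([1] * 12)
        with pytest.raises(ValueError):
            assign_heavy_light(fs, [{1, 2}, {3, 4}])

    def test_symmetric_tie_rejected(self):
        fs = make_fs([1] * 12)
        with pytest.raises(ValueError, match="degenerate"):
            assign_heavy_light(fs, [{1, 12, 6, 7}, {2, 11, 5, 8, 3, 10, 4, 9}])


class TestRepresentativeFractions:
    def test_published_h5_l10_layout(self):
        # 13C peak at fraction 5, light peak at 10
        lab = make_fs([1, 2, 3, 4, 9, 2, 2, 2, 3, 8, 2, 1])
        blk = make_fs([1, 1, 1, 1, 2, 2, 2, 2, 3, 9, 3, 1], treatment=Treatment.BLANK)
        h, l = select_representative_fractions(lab, blk, {1, 2, 3, 5}, {8, 9, 10, 11, 12})
        assert (h, l) == (5, 10)

    def test_failed_peak_falls_back_to_neighbour(self):
        lab = make_fs([1, 2, 3, 9, 3, 2, 2, 2, 3, 8, 2, 1], failed={4})
        blk = make_fs([1, 1, 1, 1, 2, 2, 2, 2, 3, 9, 3, 1], treatment=Treatment.BLANK)
        # failed fraction 4 carries the peak: nearest usable in-group,
        # heavier on ties → 3
        h, l = select_representative_fractions(lab, blk, {1, 2, 3, 4, 5}, {8, 9, 10, 11, 12})
        assert h == 3

    def test_no_heavy_peak_is_an_error(self):
        lab = make_fs([1, 1, 1, 1, 1, 2, 2, 2, 3, 9, 3, 1])
        blk = make_fs([1, 1, 1, 1, 1, 2, 2, 2, 3, 9, 3, 1], treatment=Treatment.BLANK)
        with pytest.raises(ValueError, match="no DNA peak"):
            select_representative_fractions(lab, blk, {1, 2, 3, 4, 5}, {8, 9, 10, 11, 12})

    def test_light_falls_back_to_blank_profile(self):
        lab = make_fs([1, 2, 3, 9, 3, 2, 2, 2, 2, 2, 2, 2])
        blk = make_fs([1, 1, 1, 1, 2, 2, 2, 2, 3, 9, 3, 1], treatment=Treatment.BLANK)
        h, l = select_representative_fractions(lab, blk, {1, 2, 3, 4, 5}, {8, 9, 10, 11, 12})
        assert (h, l) == (4, 10)

    def test_h_always_denser_than_l(self, clean_gradient_config):
        lab = make_fs([1, 2, 3, 9, 3, 2, 2, 2, 3, 8, 2, 1])
        blk = make_fs([1, 1, 1, 1, 2, 2, 2, 2, 3, 9, 3, 1], treatment=Treatment.BLANK)
        h, l = select_representative_fractions(lab, blk, {1, 2, 3, 4, 5}, {8, 9, 10, 11, 12})
        assert lab.by_id(h).density > lab.by_id(l).density


class TestSelectTimepoint:
    def test_estuary_worked_example(self):
        # printed H–L dissimilarities at days 1/3/4, all eligible → day 1
        records = [
            TimepointRecord(1.0, 0.7636, True, anosim_p=0.01),
            TimepointRecord(3.0, 0.6821, True, anosim_p=0.01),
            TimepointRecord(4.0, 0.5349, True, anosim_p=0.01),
        ]
        assert select_timepoint(records).chosen_t == 1.0

    def test_basin_day_two_wins_when_day_one_indistinct(self):
        records = [
            TimepointRecord(1.0, 0.80, False),
            TimepointRecord(2.0, 0.70, True),
            TimepointRecord(4.0, 0.60, True),
        ]
        assert select_timepoint(records).chosen_t == 2.0

    def test_no_eligible_timepoint_yields_diagnostic(self):
        records = [TimepointRecord(1.0, 0.9, False), TimepointRecord(4.0, 0.8, False)]
        decision = select_timepoint(records)
        assert decision.chosen_t is None
        assert "no eligible" in decision.diagnostic

    def test_alpha_gate_applies_only_when_p_known(self):
        records = [
            TimepointRecord(1.0, 0.9, True, anosim_p=0.2),
            TimepointRecord(4.0, 0.5, True, anosim_p=None),
        ]
        assert select_timepoint(records, alpha=0.05).chosen_t == 4.0

    def test_tie_breaks_to_earliest(self):
        records = [TimepointRecord(4.0, 0.7, True), TimepointRecord(1.0, 0.7, True)]
        assert select_timepoint(records).chosen_t == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_timepoint([])


class TestFractionSetValidation:
    def test_unsorted_densities_resorted_with_warning(self):
        with pytest.warns(UserWarning, match="re-sorting"):
            fs = FractionSet(
                [Fraction(3, 1.69, 1.0), Fraction(1, 1.76, 1.0), Fraction(2, 1.72, 1.0)]
            )
        assert [f.fraction_id for f in fs.fractions] == [1, 2, 3]

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            FractionSet([Fraction(1, 1.76, -1.0), Fraction(2, 1.72, 1.0)])
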