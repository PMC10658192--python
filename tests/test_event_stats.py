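import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from ept.event_stats import (
    P_VALUE_BINS,
    band_tests,
    before_after_windows,
    bonferroni,
    kruskal_wallis,
    p_value_bin,
    percent_change,
    rm_anova_total_energy,
)

from .test_timeline import make_dev_series


def brute_force_kruskal_H(*groups):
    """Independent oracle: H from first-principles rank computation with
    midranks for ties and the standard tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    s = pooled[order]
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    N = len(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    H *= 12.0 / (N * (N + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    T = np.sum(counts**3 - counts)
    return H / (1.0 - T / (N**3 - N))


class TestKruskalWallis:
    def test_identical_groups_give_zero_H(self):
        H, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert H == pytest.approx(0.0)

    def test_all_values_identical_reports_no_effect(self):
        H, p = kruskal_wallis([5, 5, 5], [5, 5])
        assert (H, p) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "groups",
        [
            ([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]),
            ([1.5, 2.5], [2.5, 3.5], [0.5, 4.5]),
            ([1, 1, 2, 3], [2, 2, 4]),
        ],
    )
    def test_H_matches_brute_force_rank_oracle(self, groups):
        H, _ = kruskal_wallis(*groups)
        assert H == pytest.approx(brute_force_kruskal_H(*groups), rel=1e-12)

    def test_null_rejection_rate_close_to_alpha(self):
        """Two i.i.d. groups of 5: rejection at alpha=0.05 should not
        exceed 0.07 (the rank statistic is slightly conservative here)."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a, b = rng.normal(size=5), rng.normal(size=5)
            _, p = kruskal_wallis(a, b)
            rejections += p < 0.05
        assert rejections / n_sim <= 0.07

    def test_needs_two_groups_and_three_obs(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])
        with pytest.raises(ValueError):
            kruskal_wallis([1], [2])


class TestBonferroni:
    def test_identity_at_family_size_one(self):
        assert np.allclose(bonferroni([0.01, 0.5], 1), [0.01, 0.5])

    def test_definition(self):
        assert bonferroni([0.01], 30)[0] == pytest.approx(0.30)

    def test_caps_at_one(self):
        assert bonferroni([0.5], 30)[0] == 1.0

    def test_adjusted_threshold_matches_three_sig_figs(self):
        assert float(f"{0.05 / 30:.3g}") == 0.00167

    @settings(deadline=None, derandomize=True)
    @given(
        p=stn.lists(stn.floats(0, 1), min_size=1, max_size=10),
        m1=stn.integers(1, 100), m2=stn.integers(1, 100),
    )
    def test_monotone_in_p_and_m(self, p, m1, m2):
        lo, hi = sorted([m1, m2])
        a, b = bonferroni(p, lo), bonferroni(p, hi)
        assert np.all(b >= a)
        assert np.all(a >= np.asarray(p))


class TestPercentChange:
    @pytest.mark.parametrize("before,after,expected", [(2, 3, 50.0), (2, 2, 0.0), (4, 1, -75.0)])
    def test_definition(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected)

    def test_zero_reference_reported_missing(self):
        assert np.isnan(percent_change(0.0, 5.0))


class TestPValueBins:
    def test_bin_edges_follow_the_significance_map(self):
        assert p_value_bin(1e-7) == 1
        assert p_value_bin(5e-6) == 2
        assert p_value_bin(5e-5) == 3
        assert p_value_bin(0.001) == 4
        assert p_value_bin(0.01) == 5
        assert P_VALUE_BINS[3] == pytest.approx(0.05 / 30)


class TestBeforeAfterWindows:
    def _series(self, event_h=50.0, n=100):
        t = np.arange(float(n))
        return make_dev_series(
            timepoints=t,
            energy=np.ones(n),
            events={"four_cell": 0.0, "heart": event_h / (n - 1), "hatch": 1.0},
        )

    def test_hourly_windows_around_event(self):
        s = self._series(event_h=50.0, n=100)
        before, after = before_after_windows(s, "heart", 5)
        assert list(s.timepoints_h[before]) == [45, 46, 47, 48, 49]
        assert list(s.timepoints_h[after]) == [50, 51, 52, 53, 54]

    def test_event_too_early_raises_for_exclusion(self):
        s = self._series(event_h=3.0)
        with pytest.raises(ValueError, match="fewer than"):
            before_after_windows(s, "heart", 5)

    def test_cardiac_band_energy_rises_when_heartbeat_injected(self):
        """Band tests detect an injected narrowband component switching
        on at the event."""
        rng = np.random.default_rng(23)
        n, n_bands, onset = 40, 12, 20
        cohort, mats = [], []
        for e in range(6):
            t = np.arange(float(n))
            bands = rng.exponential(0.1, size=(n, n_bands))
            bands[onset:, 7] += 5.0  # heartbeat band switches on
            events = {"four_cell": 0.0, "heart": onset / (n - 1), "hatch": 1.0}
            cohort.append(make_dev_series(f"e{e}", timepoints=t, energy=bands.sum(1), events=events))
            mats.append(bands)
        centres = np.arange(n_bands) * 0.1 + 0.08
        results = band_tests(cohort, mats, centres, "heart", w=5, m=n_bands)
        sig = [r for r in results if r.p_adjusted < 0.05]
        assert any(r.band_centre_hz == pytest.approx(centres[7]) for r in sig)
        assert all(r.direction == 1 for r in sig if r.band_centre_hz == pytest.approx(centres[7]))
        # non-signal bands stay quiet after correction
        assert sum(1 for r in sig if r.band_centre_hz != pytest.approx(centres[7])) == 0


class TestRmAnova:
    @staticmethod
    def _toy_table():
        # 2 species x 2 embryos x 3 timepoints, hand-chosen values
        rows = []
        values = {
            ("A", "a1"): [1.0, 2.0, 3.0],
            ("A", "a2"): [2.0, 3.0, 4.0],
            ("B", "b1"): [5.0, 6.0, 7.0],
            ("B", "b2"): [6.0, 7.0, 9.0],
        }
        for (sp, emb), vals in values.items():
            for t, v in zip([0.0, 0.5, 1.0], vals):
                rows.append(
                    {"embryo_id": emb, "species": sp, "rel_time": t, "total_energy": v}
                )
        return pd.DataFrame(rows)

    def test_species_F_matches_hand_computed_sums_of_squares(self):
        """Between-subjects F = MS_species / MS_subjects-within-species,
        computed from first principles on a balanced toy table."""
        df = self._toy_table()
        k = 3  # timepoints per embryo
        grand = df["total_energy"].mean()
        sp_means = df.groupby("species")["total_energy"].mean()
        ss_species = k * 2 * float(((sp_means - grand) ** 2).sum())
        subj_means = df.groupby("embryo_id")["total_energy"].mean()
        subj_species = df.groupby("embryo_id")["species"].first()
        ss_subj_within = k * float(
            ((subj_means - sp_means[subj_species].to_numpy()) ** 2).sum()
        )
        df_between, df_within = 2 - 1, 2 * (2 - 1)
        expected_F = (ss_species / df_between) / (ss_subj_within / df_within)
        F, d1, d2, p = rm_anova_total_energy(df)
        assert F == pytest.approx(expected_F, rel=1e-6)
        assert (d1, d2) == (df_between, df_within)

    def test_offset_between_species_detected(self):
        rng = np.random.default_rng(31)
        rows = []
        for sp, delta in (("A", 0.0), ("B", 1.0)):
            for e in range(8):
                base = rng.normal(0, 0.2)
                for t in np.linspace(0, 1, 6):
                    rows.append(
                        {"embryo_id": f"{sp}{e}", "species": sp, "rel_time": t,
                         "total_energy": np.sin(3 * t) + delta + base + rng.normal(0, 0.1)}
                    )
        F, _, _, p = rm_anova_total_energy(pd.DataFrame(rows))
        assert p < 0.001

    def test_single_species_rejected(self):
        df = self._toy_table()
        with pytest.raises(ValueError):
            rm_anova_total_energy(df[df.species == "A"])
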