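import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emomem.indices import (
    UndefinedIndexError,
    UndefinedRateError,
    adjusted_proportion,
    build_index_table,
    familiarity_dprime,
    item_dprime,
    recollection_dprime,
    source_counts,
    unbiased_hit_rate,
    z,
)
from emomem.trial_io import harmonize_judgments

from conftest import make_row, trials_frame
from helpers_oracle import oracle_indices, random_trial_fixture


class TestScalarIndices:
    @pytest.mark.parametrize("s,n,expected", [
        (24, 48, 0.5),
        (0, 48, 1 / 96),
        (48, 48, 1 - 1 / 96),
        (1, 4, 0.25),
    ])
    def test_adjusted_proportion(self, s, n, expected):
        assert adjusted_proportion(s, n) == pytest.approx(expected, abs=1e-15)

    def test_adjusted_proportion_zero_trials(self):
        with pytest.raises(UndefinedRateError):
            adjusted_proportion(0, 0)

    @pytest.mark.parametrize("p,expected", [
        (0.5, 0.0),
        (0.8413, 0.9998150936147446),   # quantile oracle, ~1.000
        (0.0228, -1.99907721497177),    # quantile oracle, ~-2.000
    ])
    def test_normal_quantile(self, p, expected):
        assert z(p) == pytest.approx(expected, abs=1e-9)
        assert z(1 - p) == pytest.approx(-expected, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_quantile_domain(self, p):
        with pytest.raises(UndefinedIndexError):
            z(p)

    @pytest.mark.parametrize("hr,fr,expected", [
        (0.84, 0.16, 1.988915766419506),
        (0.3, 0.3, 0.0),
        # perfect hits (48/48) and zero FAs (0/144) after 1/(2N) adjustment
        (1 - 1 / 96, 1 / 288, 5.010488038482395),
    ])
    def test_item_dprime(self, hr, fr, expected):
        assert item_dprime(hr, fr) == pytest.approx(expected, abs=1e-9)
        assert item_dprime(fr, hr) == pytest.approx(-expected, abs=1e-9)

    def test_recollection_dprime_matches_item_form(self):
        assert recollection_dprime(0.5, 0.5) == 0.0
        assert recollection_dprime(0.84, 0.16) == pytest.approx(
            item_dprime(0.84, 0.16), abs=1e-15)
        # zero remember-FA counts are adjusted to 1/(2N) first, so finite
        assert math.isfinite(recollection_dprime(0.84, adjusted_proportion(0, 90)))

    @pytest.mark.parametrize("rh,kh,rf,kf,expected", [
        (0.5, 0.25, 0.2, 0.4, 0.0),          # both conditional ratios 0.5
        (0.6, 0.3, 0.1, 0.09, 1.956041315740682),  # z(0.75) - z(0.1)
    ])
    def test_familiarity_dprime(self, rh, kh, rf, kf, expected):
        assert familiarity_dprime(rh, kh, rf, kf) == pytest.approx(expected, abs=1e-9)

    def test_familiarity_dprime_invalid_ratio(self):
        with pytest.raises(UndefinedIndexError):
            familiarity_dprime(0.5, 0.6, 0.1, 0.05)  # K/(1-R) = 1.2

    @pytest.mark.parametrize("h,i,c,expected", [
        (3, 1, 6, 0.375),
        (7, 0, 7, 1.0),
        (0, 5, 3, 0.0),
    ])
    def test_unbiased_hit_rate(self, h, i, c, expected):
        assert unbiased_hit_rate(h, i, c) == pytest.approx(expected, abs=1e-15)

    def test_unbiased_hit_rate_missing_and_invalid(self):
        assert math.isnan(unbiased_hit_rate(0, 5, 0))
        assert math.isnan(unbiased_hit_rate(0, 0, 4))
        with pytest.raises(ValueError):
            unbiased_hit_rate(-1, 0, 1)

    @given(h=st.integers(0, 50), i=st.integers(0, 50), extra=st.integers(0, 50))
    @settings(deadline=None, max_examples=200)
    def test_hu_bounded_by_accuracy_and_precision(self, h, i, extra):
        """Hu = accuracy x precision, so it never exceeds either factor."""
        chosen = h + extra
        hu = unbiased_hit_rate(h, i, chosen)
        if math.isnan(hu):
            assert h + i == 0 or chosen == 0
        else:
            assert 0.0 <= hu <= 1.0
            assert hu <= h / (h + i) + 1e-12
            assert hu <= h / chosen + 1e-12


class TestSourceCounts:
    def test_worked_enumeration(self):
        """4 old neutral know items, 3 attributed neutral, 1 pleasant; no other
        neutral attribution under know: hits 3, incorrect 1, chosen 3."""
        rows = [
            make_row(item_id=f"o{i}", context_category="neutral",
                     recognition_response="know",
                     source_response="neutral" if i < 3 else "pleasant")
            for i in range(4)
        ]
        rows.append(make_row(item_id="o4", context_category="pleasant",
                             recognition_response="remember", source_response="pleasant"))
        rows.append(make_row(item_id="n0", item_status="new", context_category=None,
                             recognition_response="new", source_response=None))
        counts = source_counts(harmonize_judgments(trials_frame(rows)), by_memory_type=True)
        row = counts.set_index(["memory_type", "context_category"]).loc[("know", "neutral")]
        assert (row["hits"], row["incorrect"], row["times_chosen"]) == (3, 1, 3)

    def test_empty_stratum_yields_zero_counts(self, rk_participant_trials):
        counts = source_counts(harmonize_judgments(rk_participant_trials),
                               by_memory_type=True)
        know_pleasant = counts.set_index(["memory_type", "context_category"]).loc[
            ("know", "pleasant")]
        # no pleasant item was judged know, but one know attribution named pleasant
        assert know_pleasant[["hits", "incorrect", "times_chosen"]].tolist() == [0, 0, 1]

    def test_no_know_judgments_all_know_counts_zero(self):
        rows = [make_row(item_id=f"o{i}", context_category=c,
                         recognition_response="remember", source_response=c)
                for i, c in enumerate(["neutral", "pleasant"])]
        counts = source_counts(harmonize_judgments(trials_frame(rows)),
                               by_memory_type=True)
        know = counts[counts["memory_type"] == "know"]
        assert (know[["hits", "incorrect", "times_chosen"]] == 0).all().all()

    def test_false_alarm_attributions_excluded(self, rk_participant_trials):
        """The know false alarm attributed 'pleasant' must not enter counts."""
        counts = source_counts(harmonize_judgments(rk_participant_trials),
                               by_memory_type=True)
        total_chosen = counts["times_chosen"].sum()
        # only the 6 old items carry attributions; the FA contributes nothing
        assert total_chosen == 6


class TestBuildIndexTable:
    def test_rk_participant_row_layout(self, rk_participant_trials):
        table = build_index_table(rk_participant_trials)
        by_type = table.groupby("memory_type").size().to_dict()
        assert by_type == {"overall": 2, "remember": 2, "know": 2}

    def test_old_new_participant_has_no_memory_type_rows(self):
        rows = [
            make_row(study="S4", retrieval_task="old_new", item_id=f"o{i}",
                     context_category=c, recognition_response="old", source_response=c)
            for i, c in enumerate(["unpleasant", "neutral"] * 2)
        ] + [
            make_row(study="S4", retrieval_task="old_new", item_id=f"n{i}",
                     item_status="new", context_category=None,
                     recognition_response="new", source_response=None)
            for i in range(3)
        ]
        table = build_index_table(trials_frame(rows))
        assert set(table["memory_type"]) == {"overall"}
        assert len(table) == 2
        assert set(table["affective_category"]) == {"unpleasant", "neutral"}

    def test_undefined_conditional_cell_is_missing_not_zero(self, rk_participant_trials):
        table = build_index_table(rk_participant_trials).set_index(
            ["memory_type", "affective_category"])
        assert math.isnan(table.loc[("know", "pleasant"), "hu"])

    def test_zero_new_trials_is_an_error(self):
        rows = [make_row()]
        with pytest.raises(UndefinedRateError, match="no new trials"):
            build_index_table(trials_frame(rows))

    def test_invariant_to_trial_order_and_item_relabeling(self, rk_participant_trials):
        table = build_index_table(rk_participant_trials)
        shuffled = rk_participant_trials.sample(frac=1.0, random_state=7).copy()
        shuffled["item_id"] = [f"x{i}" for i in range(len(shuffled))]
        table2 = build_index_table(shuffled)
        pd.testing.assert_frame_equal(table, table2)

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        """Vectorized scoring equals independent enumeration to 1e-12."""
        for _ in range(25):
            trials = random_trial_fixture(rng)
            expected = oracle_indices(trials)
            table = build_index_table(trials_frame(trials))
            got = {
                (r.participant, r.memory_type, r.affective_category):
                    {"d_prime": r.d_prime, "hu": r.hu}
                for r in table.itertuples()
            }
            assert set(got) == set(expected)
            for key, exp in expected.items():
                for name in ("d_prime", "hu"):
                    e, g = exp[name], got[key][name]
                    if e is None or (isinstance(e, float) and math.isnan(e)):
                        assert math.isnan(g), (key, name)
                    else:
                        assert g == pytest.approx(e, abs=1e-12), (key, name)

    def test_overall_dprime_consistent_with_memory_type_rates(self, rng):
        """For R/K data, z-transformed remember+know counts reproduce the
        overall d' computed from harmonized old judgments."""
        rk = None
        for _ in range(10):
            trials = random_trial_fixture(rng)
            df = harmonize_judgments(trials_frame(trials))
            if (df["retrieval_task"] == "remember_know").all():
                rk = df
                break
        assert rk is not None
        table = build_index_table(rk).set_index(
            ["participant", "memory_type", "affective_category"])
        for (p, cat), grp in rk[rk.item_status == "old"].groupby(
                ["participant", "context_category"]):
            news = rk[(rk.participant == p) & (rk.item_status == "new")]
            hits = int(grp.old_judgment.sum())
            d = item_dprime(adjusted_proportion(hits, len(grp)),
                            adjusted_proportion(int(news.old_judgment.sum()), len(news)))
            assert table.loc[(p, "overall", cat), "d_prime"] == pytest.approx(d, abs=1e-12)
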