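"""Generator: determinism, prevalence recovery, independence under the null,
planted-signal structure, and the CSV round trip."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import riskcast as rc
from riskcast import preprocess, synth
from riskcast.synth import RecordsError

from conftest import make_records


def daily_presence(records, truth, channel):
    """Day-indicator vector for one subject/channel from the long table."""
    m = preprocess.aggregate_daily(
        records, [channel], truth.start_date, truth.n_days, truth.subject_ids[0]
    )
    return m.values[:, 0]


class TestSamplePopulation:
    def test_identical_config_gives_identical_records(self, tiny_population):
        cfg, records, truth = tiny_population
        again, truth2 = rc.sample_population(cfg)
        pd.testing.assert_frame_equal(records, again)
        assert np.array_equal(truth.baseline_logits, truth2.baseline_logits)
        assert truth.group == truth2.group

    def test_prevalence_recovers_baseline_rate(self):
        # no coupling, fixed baseline: empirical daily rate within 3 binomial
        # SEs of the logistic of the baseline logit
        p = 0.3
        cfg = rc.null_preset(
            n_subjects=1, n_days=2000,
            baseline_logit_mean=np.log(p / (1 - p)), baseline_logit_sd=0.0,
            seed=5,
        )
        records, truth = rc.sample_population(cfg)
        se = np.sqrt(p * (1 - p) / cfg.n_days)
        for channel in ("Aggression", "Task Refusal"):
            rate = daily_presence(records, truth, channel).mean()
            assert abs(rate - p) < 3 * se
        # the seizure channel is aggregated separately; count distinct days
        seiz_days = records.loc[records.behavior == "Seizure", "date"].nunique()
        assert abs(seiz_days / cfg.n_days - p) < 3 * se

    def test_channels_uncorrelated_without_coupling(self):
        cfg = rc.null_preset(
            n_subjects=1, n_days=2000,
            baseline_logit_mean=0.0, baseline_logit_sd=0.0, seed=6,
        )
        records, truth = rc.sample_population(cfg)
        a = daily_presence(records, truth, "Aggression")
        b = daily_presence(records, truth, "Disruptive Behavior")
        # lag-1 cross-correlation within 3 SEs of zero (n-1 paired days)
        n = len(a) - 1
        r = np.corrcoef(a[:-1], b[1:])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_zero_rate_gives_empty_table(self):
        cfg = rc.null_preset(
            n_subjects=1, n_days=1, baseline_logit_mean=-60.0,
            baseline_logit_sd=0.0, seed=1,
        )
        records, _ = rc.sample_population(cfg)
        assert len(records) == 0

    def test_rows_unique_and_shifts_valid(self, tiny_population):
        _, records, _ = tiny_population
        key = ["subject_id", "date", "shift", "behavior"]
        assert not records.duplicated(subset=key).any()
        assert records["shift"].isin(synth.SHIFTS).all()

    def test_severe_rate_matches_config(self):
        cfg = rc.null_preset(n_subjects=2, n_days=900, severe_prob=0.25, seed=9)
        records, _ = rc.sample_population(cfg)
        rate = records["severe"].mean()
        assert abs(rate - 0.25) < 3 * np.sqrt(0.25 * 0.75 / len(records))

    def test_group_labels_drawn_with_proportions(self):
        cfg = rc.null_preset(n_subjects=200, n_days=1, seed=2)
        _, truth = rc.sample_population(cfg)
        frac_female = np.mean([g == "female" for g in truth.group.values()])
        assert abs(frac_female - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 200)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rc.GeneratorConfig(n_subjects=0).validate()
        with pytest.raises(ValueError):
            rc.GeneratorConfig(shift_split=(0.0, 0.0, 0.0)).validate()
        with pytest.raises(ValueError):
            rc.GeneratorConfig(severe_prob=1.5).validate()
        with pytest.raises(ValueError):
            bad = np.full((11, 1, 11), np.inf)
            rc.GeneratorConfig(coupling=bad).validate()


class TestPresets:
    def test_null_preset_has_no_structure(self):
        cfg = rc.null_preset()
        assert np.all(cfg.coupling_tensor() == 0)
        assert cfg.cycle_amplitude == 0.0

    def test_null_preset_is_pure(self):
        a, b = rc.null_preset(seed=3), rc.null_preset(seed=3)
        assert np.array_equal(a.coupling_tensor(), b.coupling_tensor())
        assert dataclasses.replace(a, coupling=None) == dataclasses.replace(
            b, coupling=None
        )

    def test_zero_strength_equals_null(self):
        # same generative law: both couplings vanish identically
        s = rc.signal_preset(0.0, n_subjects=2, n_days=120, seed=4)
        n = rc.null_preset(n_subjects=2, n_days=120, seed=4)
        assert np.all(s.coupling_tensor() == 0)
        assert np.all(n.coupling_tensor() == 0)
        ra, _ = rc.sample_population(s)
        rb, _ = rc.sample_population(n)
        pd.testing.assert_frame_equal(ra, rb)

    def test_conditional_gap_matches_logistic_closed_form(self):
        # Fixed baselines, planted coupling: P(target | trigger history)
        # follows the logistic model exactly, so the empirical conditional
        # probabilities must match sigmoid(b + sum of active lag weights).
        strength, b_t, b_d = 2.0, -1.0, -0.3
        means = {c: -2.0 for c in synth.DEFAULT_CHANNELS}
        means["Aggression"] = b_t
        means[synth.SIGNAL_TRIGGER] = b_d
        cfg = rc.signal_preset(
            strength,
            n_subjects=1, n_days=20000,
            baseline_logit_mean=[means[c] for c in synth.DEFAULT_CHANNELS],
            baseline_logit_sd=0.0,
            seed=11,
        )
        records, truth = rc.sample_population(cfg)
        trig = daily_presence(records, truth, synth.SIGNAL_TRIGGER)
        tgt = daily_presence(records, truth, "Aggression")
        w = cfg.coupling_tensor()
        src = synth.DEFAULT_CHANNELS.index(synth.SIGNAL_TRIGGER)
        dst = synth.DEFAULT_CHANNELS.index("Aggression")
        lags = w[src, :, dst]  # (strength, strength/2, strength/4)
        # condition on the exact 3-day trigger history
        for h in [(1, 0, 0), (1, 1, 1), (0, 0, 0)]:
            mask = np.ones(len(tgt), dtype=bool)
            mask[:3] = False
            for lag, val in enumerate(h, start=1):
                mask[3:] &= np.roll(trig, lag)[3:] == val
            n = mask.sum()
            assert n > 200
            expected = expit(b_t + float(np.dot(lags, h)))
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(tgt[mask].mean() - expected) < 3.5 * se

    def test_gap_monotone_in_strength(self):
        # common seed across strengths: triggered-vs-untriggered gap in the
        # target channel never decreases as the planted strength grows
        gaps = []
        for s in (0.5, 2.0, 6.0):
            cfg = rc.signal_preset(s, n_subjects=1, n_days=4000,
                                   baseline_logit_sd=0.0, seed=77)
            records, truth = rc.sample_population(cfg)
            trig = daily_presence(records, truth, synth.SIGNAL_TRIGGER)
            tgt = daily_presence(records, truth, "Aggression")
            prev = trig[:-1].astype(bool)
            gaps.append(tgt[1:][prev].mean() - tgt[1:][~prev].mean())
        assert gaps[0] <= gaps[1] <= gaps[2]
        # logistic saturation: with a huge increment the triggered-day
        # probability approaches 1
        cfg = rc.signal_preset(6.0, n_subjects=1, n_days=4000,
                               baseline_logit_sd=0.0, seed=77)
        records, truth = rc.sample_population(cfg)
        trig = daily_presence(records, truth, synth.SIGNAL_TRIGGER)
        tgt = daily_presence(records, truth, "Aggression")
        assert tgt[1:][trig[:-1].astype(bool)].mean() > 0.9


class TestRecordsIO:
    def test_round_trip_identity(self, tmp_path):
        table = make_records([
            ("S1", "2020-01-01", "morning", "Aggression", True),
            ("S1", "2020-01-01", "afternoon", "Aggression", False),
            ("S2", "2020-01-03", "overnight", "Seizure", False),
        ])
        path = tmp_path / "records.csv"
        rc.write_records(table, path)
        back = rc.read_records(path)
        pd.testing.assert_frame_equal(back, table)

    def test_duplicate_key_reports_row(self, tmp_path):
        table = make_records([
            ("S1", "2020-01-01", "morning", "Aggression", False),
            ("S1", "2020-01-01", "morning", "Aggression", True),
        ])
        path = tmp_path / "dup.csv"
        table.to_csv(path, index=False)
        with pytest.raises(RecordsError, match=r"duplicate.*\[1, 2\]"):
            rc.read_records(path)

    def test_unknown_shift_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,date,shift,behavior,severe\n"
            "S1,2020-01-01,night,Aggression,False\n"
        )
        with pytest.raises(RecordsError, match="shift"):
            rc.read_records(path)

    def test_header_only_file_is_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("subject_id,date,shift,behavior,severe\n")
        assert len(rc.read_records(path)) == 0

    def test_population_round_trip(self, tiny_population, tmp_path):
        _, records, _ = tiny_population
        path = tmp_path / "pop.csv"
        rc.write_records(records, path)
        back = rc.read_records(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), records.reset_index(drop=True)
        )
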