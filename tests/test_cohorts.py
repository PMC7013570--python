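"""Record cleaning, cohort selection and observation windows."""

import numpy as np
import pandas as pd
import pytest

from comorbnet import (
    build_histories,
    clean_records,
    first_diagnosis,
    membership_table,
    read_episode_table,
    sample_equal,
    select_cohorts,
)
from comorbnet.cohorts import CohortSelection, ObservationWindow


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "episode_id", "admit_date", "icd_code"],
    )


def _history(tables, spec):
    """spec: list of (episode_id, date, [codes]) for one patient."""
    rows = [
        ("p1", eid, day, ";".join(codes)) for eid, day, codes in spec
    ]
    episodes, _ = read_episode_table(_table(rows))
    cleaned, _ = clean_records(episodes, tables.exclusions)
    return build_histories(cleaned).get("p1")


T2DM_CODE = "E11.2"
CVD_CODE = "I50.9"
COMORBIDITY_CODE = "N18.9"  # renal failure


class TestReading:
    def test_long_and_list_formats_agree(self):
        long = _table(
            [
                ("p", "e1", "2010-01-01", "E11.2"),
                ("p", "e1", "2010-01-01", "N18.9"),
            ]
        )
        packed = _table([("p", "e1", "2010-01-01", "E11.2;N18.9")])
        eps_long, _ = read_episode_table(long)
        eps_packed, _ = read_episode_table(packed)
        assert eps_long == eps_packed
        assert len(eps_long) == 1
        assert len(eps_long[0].codes) == 2

    def test_bad_rows_and_codes_are_counted_not_fatal(self):
        df = _table(
            [
                ("p", "e1", "2010-01-01", "E11.2"),
                ("p", "e2", "not-a-date", "E11.2"),
                ("p", "e3", "2010-01-02", "???"),
            ]
        )
        episodes, stats = read_episode_table(df)
        assert stats["rows_skipped"] == 1
        assert stats["codes_skipped"] == 1
        assert {e.episode_id for e in episodes} == {"e1", "e3"}

    def test_missing_required_column_raises(self):
        with pytest.raises(ValueError, match="missing required"):
            read_episode_table(pd.DataFrame({"patient_id": ["p"]}))


class TestCleaning:
    def test_duplicate_rows_collapse(self, tables):
        df = _table(
            [
                ("p", "e1", "2010-01-01", "E11.2"),
                ("p", "e1", "2010-01-01", "E11.2"),
            ]
        )
        episodes, _ = read_episode_table(df)
        cleaned, stats = clean_records(episodes, tables.exclusions)
        assert len(cleaned) == 1

    def test_injury_only_episode_dropped(self, tables):
        df = _table([("p", "e1", "2010-01-01", "S42.0")])
        episodes, _ = read_episode_table(df)
        cleaned, stats = clean_records(episodes, tables.exclusions)
        assert cleaned == []
        assert stats["codes_excluded"] == 1
        assert stats["episodes_dropped"] == 1

    def test_retention_count_on_mixed_fixture(self, tables):
        # 5 episode records: one duplicate pair, one all-excluded -> 3 retained
        df = _table(
            [
                ("p", "e1", "2010-01-01", "E11.2"),
                ("p", "e2", "2010-02-01", "S42.0;R50.9"),
                ("p", "e3", "2010-03-01", "N18.9"),
                ("p", "e4", "2010-04-01", "I50.9;S42.0"),
            ]
        )
        episodes, _ = read_episode_table(df)
        cleaned, stats = clean_records(episodes + [episodes[0]], tables.exclusions)
        assert len(cleaned) == 3
        assert stats["duplicates_collapsed"] == 1
        assert stats["episodes_dropped"] == 1

    def test_cleaning_is_idempotent(self, tables):
        df = _table(
            [
                ("p", "e1", "2010-01-01", "E11.2;S42.0"),
                ("p", "e2", "2010-02-01", "R50.9"),
                ("q", "e1", "2010-01-05", "N18.9"),
            ]
        )
        episodes, _ = read_episode_table(df)
        once, _ = clean_records(episodes, tables.exclusions)
        twice, stats = clean_records(once, tables.exclusions)
        assert once == twice
        assert stats["codes_excluded"] == 0
        assert stats["episodes_dropped"] == 0


class TestFirstDiagnosis:
    def test_earliest_match_and_none(self, tables, t2dm, cvd):
        history = _history(
            tables,
            [
                ("e1", "2010-01-01", ["N18.9"]),
                ("e2", "2010-02-01", [T2DM_CODE]),
                ("e3", "2010-03-01", ["N18.9"]),
                ("e4", "2010-04-01", [T2DM_CODE]),
            ],
        )
        idx, day = first_diagnosis(history, t2dm)
        assert idx == 1
        assert day.isoformat() == "2010-02-01"
        assert first_diagnosis(history, cvd) is None


def _select(tables, patients):
    """patients: {pid: [(eid, date, codes)]} → cohort selections."""
    rows = []
    for pid, spec in patients.items():
        for eid, day, codes in spec:
            rows.append((pid, eid, day, ";".join(codes)))
    episodes, _ = read_episode_table(_table(rows))
    cleaned, _ = clean_records(episodes, tables.exclusions)
    return select_cohorts(
        build_histories(cleaned),
        tables.index_diseases["T2DM"],
        tables.index_diseases["CVD"],
        tables.comorbidities,
    )


class TestSelection:
    def test_prototypical_members(self, tables):
        ab, a_only, funnel = _select(
            tables,
            {
                "dual": [
                    ("e1", "2010-01-01", [T2DM_CODE]),
                    ("e2", "2010-06-01", [COMORBIDITY_CODE]),
                    ("e3", "2011-01-01", [CVD_CODE]),
                ],
                "single": [
                    ("e1", "2009-01-01", [COMORBIDITY_CODE]),
                    ("e2", "2010-01-01", [T2DM_CODE]),
                ],
            },
        )
        assert set(ab.members) == {"dual"}
        assert set(a_only.members) == {"single"}
        window = ab.members["dual"].qualifying_episodes
        # inclusive of the first-T2DM episode, exclusive of the CVD episode
        assert [e.episode_id for e in window] == ["e1", "e2"]
        assert all(
            ab.members["dual"].first_A_date <= e.admit_date
            < ab.members["dual"].first_B_date
            for e in window
        )
        assert all(
            e.admit_date < a_only.members["single"].first_A_date
            for e in a_only.members["single"].qualifying_episodes
        )

    def test_same_episode_diagnoses_in_neither_cohort(self, tables):
        ab, a_only, _ = _select(
            tables,
            {
                "p": [
                    ("e1", "2010-01-01", [T2DM_CODE, CVD_CODE]),
                    ("e2", "2010-06-01", [COMORBIDITY_CODE]),
                    ("e3", "2011-01-01", [CVD_CODE]),
                ]
            },
        )
        assert not ab.members and not a_only.members

    def test_dual_requires_comorbidity_between_diagnoses(self, tables):
        ab, _, _ = _select(
            tables,
            {
                "p": [
                    ("e1", "2010-01-01", [T2DM_CODE]),
                    ("e2", "2010-06-01", ["Z99.9"]),  # unmapped code only
                    ("e3", "2011-01-01", [CVD_CODE]),
                ]
            },
        )
        assert not ab.members

    def test_dual_requires_admission_strictly_between(self, tables):
        ab, _, _ = _select(
            tables,
            {
                "p": [
                    ("e1", "2010-01-01", [T2DM_CODE, COMORBIDITY_CODE]),
                    ("e2", "2011-01-01", [CVD_CODE]),
                ]
            },
        )
        assert not ab.members

    def test_single_requires_comorbidity_before_first_diagnosis(self, tables):
        _, a_only, _ = _select(
            tables,
            {
                "p": [
                    ("e1", "2009-01-01", ["Z99.9"]),
                    ("e2", "2010-01-01", [T2DM_CODE]),
                    ("e3", "2011-01-01", [COMORBIDITY_CODE]),  # too late
                ]
            },
        )
        assert not a_only.members

    def test_any_cvd_code_removes_from_single_cohort(self, tables):
        base = [
            ("e1", "2009-01-01", [COMORBIDITY_CODE]),
            ("e2", "2010-01-01", [T2DM_CODE]),
        ]
        _, a_only, _ = _select(tables, {"p": base})
        assert "p" in a_only.members
        _, a_only, _ = _select(
            tables, {"p": base + [("e0", "2008-01-01", [CVD_CODE])]}
        )
        assert "p" not in a_only.members

    def test_cohorts_are_disjoint_on_synthetic_data(self, small_run):
        ab, a_only = small_run["cohorts"]
        assert not (set(ab.members) & set(a_only.members))
        for window in ab.members.values():
            for ep in window.qualifying_episodes:
                assert window.first_A_date <= ep.admit_date < window.first_B_date
        for window in a_only.members.values():
            for ep in window.qualifying_episodes:
                assert ep.admit_date < window.first_A_date


class TestSampling:
    def _cohort(self, n):
        return CohortSelection(
            label="x",
            members={
                f"p{i}": ObservationWindow(patient_id=f"p{i}", qualifying_episodes=[])
                for i in range(n)
            },
        )

    def test_identity_and_determinism(self):
        cohort = self._cohort(5)
        assert set(sample_equal(cohort, 5, 0).members) == set(cohort.members)
        first = sample_equal(cohort, 3, 7)
        second = sample_equal(cohort, 3, 7)
        assert set(first.members) == set(second.members)

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            sample_equal(self._cohort(3), 4, 0)

    def test_membership_frequency_is_uniform(self):
        """P(member sampled) ≈ n/size within 3 standard errors."""
        cohort = self._cohort(6)
        n, trials = 3, 10_000
        counts = {pid: 0 for pid in cohort.members}
        for seed in range(trials):
            for pid in sample_equal(cohort, n, seed).members:
                counts[pid] += 1
        p = n / len(cohort)
        se = np.sqrt(p * (1 - p) / trials)
        for pid, c in counts.items():
            assert abs(c / trials - p) < 3 * se, pid


def test_membership_table_shape(small_run):
    ab, a_only = small_run["cohorts"]
    df = membership_table(ab, a_only)
    assert len(df) == len(ab) + len(a_only)
    assert (df.loc[df.cohort == ab.label, "first_B_date"].notna()).all()
    assert (df["n_qualifying_episodes"] >= 1).all()
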