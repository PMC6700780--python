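"""Joint-table reconstruction and the synthetic cohort generators."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from crcside import assign_side
from crcside.metrics import AlignmentError, cross_tabulate
from crcside.synthetic import (
    FIXTURE_DEMOGRAPHICS,
    ICD10_TRANSITION,
    CohortConfig,
    joint_table_oracle,
    reconstruct_fixture,
    sample_cohort,
)

#: The expected contingency table, derived by an independent pencil-and-
#: paper integer search over the published margins and rounding windows
#: before the in-package search was implemented (rows LEFT, RIGHT,
#: TRANSVERSE, UNSPECIFIED, RECTUM, MULTIPLE[RIGHT+TRANSVERSE]; columns
#: LEFT, RIGHT, TRANSVERSE, UNSPECIFIED).
EXPECTED_JOINT = [
    [62, 0, 0, 8],
    [0, 33, 1, 1],
    [3, 0, 7, 0],
    [25, 34, 4, 13],
    [8, 0, 0, 0],
    [1, 0, 0, 0],
]


class TestJointTableOracle:
    def test_matches_independent_derivation(self):
        jt = joint_table_oracle()
        assert jt.counts.to_numpy().tolist() == EXPECTED_JOINT

    def test_margins_and_pinned_cells(self):
        jt = joint_table_oracle()
        assert jt.n == 200
        assert jt.counts.sum(axis=1).tolist() == [70, 35, 10, 76, 8, 1]
        assert jt.counts.sum(axis=0).tolist() == [99, 67, 12, 22]
        c = jt.counts
        assert int(c.loc["LEFT", "LEFT"]) == 62
        assert int(c.loc["RIGHT", "RIGHT"]) == 33
        assert int(c.loc["TRANSVERSE", "TRANSVERSE"]) == 7
        assert int(c.loc["UNSPECIFIED", "UNSPECIFIED"]) == 13
        # exactly one cross-match between right- and transverse-involved cells
        cross = (
            int(c.loc["RIGHT", "TRANSVERSE"])
            + int(c.loc["TRANSVERSE", "RIGHT"])
            + int(c.loc["MULTIPLE[RIGHT+TRANSVERSE]", "RIGHT"])
            + int(c.loc["MULTIPLE[RIGHT+TRANSVERSE]", "TRANSVERSE"])
        )
        assert cross == 1


class TestFixture:
    def test_roundtrip_every_patient(self, fixture_dataset, fixture_assigned):
        for pid, intended in fixture_dataset.intended.items():
            assert fixture_assigned[pid].label == intended

    def test_assigned_margins(self, fixture_crosstab):
        assert fixture_crosstab.counts.to_numpy().tolist() == EXPECTED_JOINT

    def test_abstraction_block(self, fixture_dataset):
        counts = pd.Series(fixture_dataset.abstraction).value_counts()
        assert counts.to_dict() == {
            "LEFT": 99,
            "RIGHT": 67,
            "TRANSVERSE": 12,
            "UNSPECIFIED": 22,
        }

    def test_demographic_blocks_exact(self, fixture_dataset):
        demo = fixture_dataset.demographics
        for var, expected in FIXTURE_DEMOGRAPHICS.items():
            assert demo[var].value_counts().to_dict() == expected

    def test_same_seed_byte_identical(self):
        frames_a = reconstruct_fixture(5).to_frames()
        frames_b = reconstruct_fixture(5).to_frames()
        for a, b in zip(frames_a, frames_b):
            assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_margins_stable_across_seeds(self):
        ds = reconstruct_fixture(99)
        assigned = {tl.patient_id: assign_side(tl) for tl in ds.patients}
        ct = cross_tabulate(assigned, ds.abstraction)
        assert ct.counts.to_numpy().tolist() == EXPECTED_JOINT

    def test_icd_revision_follows_event_date(self, fixture_dataset):
        for tl in fixture_dataset.patients:
            for e in tl.events:
                if e.event_date is None:
                    continue
                is_icd10 = e.code.canonical[0].isalpha()
                assert is_icd10 == (e.event_date >= ICD10_TRANSITION)

    def test_unspecified_patients_can_carry_specific_codes_off_index(
        self, fixture_dataset, fixture_assigned
    ):
        # the index-only rule must actually be exercised
        found = False
        for tl in fixture_dataset.patients:
            if fixture_assigned[tl.patient_id].category.value != "UNSPECIFIED":
                continue
            index_date = fixture_assigned[tl.patient_id].index_date
            for e in tl.events:
                if e.event_date != index_date and e.code.canonical not in ("1539", "C189"):
                    found = True
        assert found

    def test_contains_equidistant_tie_case(self, fixture_dataset):
        tie = next(tl for tl in fixture_dataset.patients if tl.patient_id == "P0001")
        anchor = tie.initial_diagnosis_date
        offsets = sorted((e.event_date - anchor).days for e in tie.events)
        assert -offsets[0] in [o for o in offsets if o > 0]


class TestSampleCohort:
    def test_roundtrip_constructive(self):
        ds = sample_cohort(CohortConfig(n=2000, seed=3))
        for tl in ds.patients:
            assert assign_side(tl).label == ds.intended[tl.patient_id]

    def test_all_specific_when_forced(self):
        ds = sample_cohort(CohortConfig(n=500, p_specific_code=1.0, seed=4))
        assert all(lab != "UNSPECIFIED" for lab in ds.intended.values())

    def test_empty_cohort(self):
        ds = sample_cohort(CohortConfig(n=0, seed=1))
        assert ds.n == 0
        with pytest.raises(AlignmentError):
            cross_tabulate(ds.intended, ds.abstraction)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n=10, joint={("LEFT", "LEFT"): 0.5}).validate()
        with pytest.raises(ValueError):
            CohortConfig(n=10, p_missing_diagnosis_date=1.5).validate()
        with pytest.raises(ValueError):
            CohortConfig(n=-1).validate()

    def test_empirical_joint_converges(self):
        # seed-averaged total-variation distance to the configured joint
        tvs = []
        for seed in range(5):
            config = CohortConfig(n=100_000, seed=seed)
            ds = sample_cohort(config)
            joint = config.resolved_joint()
            counts = {}
            for pid, assigned in ds.intended.items():
                key = (ds.abstraction[pid], assigned)
                counts[key] = counts.get(key, 0) + 1
            tvs.append(
                0.5
                * sum(abs(counts.get(cell, 0) / config.n - p) for cell, p in joint.items())
            )
        assert np.mean(tvs) < 0.02

    def test_extra_covariates_carried_inert(self):
        config = CohortConfig(
            n=50,
            seed=2,
            extra_covariates={"kras": {"positive": 0.4, "negative": 0.6}},
        )
        ds = sample_cohort(config)
        assert set(ds.demographics["kras"]) <= {"positive", "negative"}
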