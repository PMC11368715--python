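"""Domain types, event-record IO, and M1 handling of BQL observations."""

import io

import numpy as np
import pytest

from voripk.records import (CovariateSet, DoseEvent, Observation,
                            SchemaError, SubjectRecord, ValidationError,
                            apply_m1, read_dataset, write_dataset)

COV = dict(AGE=70.0, WT=65.0, SEX="male", ALB=34.8, CRP=59.0, phenotype="NM")


def make_subject(sid="S1", obs_times=(120.0,), conc=4.0):
    return SubjectRecord(
        id=sid, covariates=CovariateSet(**COV),
        doses=(DoseEvent(0.0, 200.0, "intravenous", 2.0, interval=12.0,
                         n_doses=12),),
        observations=tuple(Observation(t, conc) for t in obs_times))


class TestDomainTypes:
    def test_dose_event_invariants(self):
        with pytest.raises(ValidationError):
            DoseEvent(0.0, -5.0, "oral")
        with pytest.raises(ValidationError):
            DoseEvent(0.0, 200.0, "intravenous", 0.0)  # IV needs a duration
        with pytest.raises(ValidationError):
            DoseEvent(0.0, 200.0, "oral", 2.0)  # oral must not have one
        with pytest.raises(ValidationError):
            DoseEvent(0.0, 200.0, "oral", interval=0.0, n_doses=3)

    def test_dose_expand_shorthand(self):
        d = DoseEvent(24.0, 200.0, "oral", interval=12.0, n_doses=3)
        times = [e.time for e in d.expand()]
        assert times == [24.0, 36.0, 48.0]
        assert all(e.n_doses == 1 for e in d.expand())

    def test_bql_flag_derived_from_lloq(self):
        assert Observation(12.0, 0.05, lloq=0.1).bql_flag is True
        assert Observation(12.0, 2.5, lloq=0.1).bql_flag is False
        with pytest.raises(ValidationError):
            Observation(12.0, 0.05, lloq=0.1, bql_flag=False)

    def test_covariates_validated(self):
        with pytest.raises(ValidationError):
            CovariateSet(**{**COV, "CRP": -1.0})
        with pytest.raises(ValidationError):
            CovariateSet(**{**COV, "phenotype": "UM"})

    def test_observation_ordering_enforced(self):
        with pytest.raises(ValidationError):
            make_subject(obs_times=(120.0, 120.0))
        with pytest.raises(ValidationError):
            make_subject(obs_times=(120.0, 96.0))

    def test_observation_requires_preceding_dose(self):
        with pytest.raises(ValidationError):
            SubjectRecord(id="S1", covariates=CovariateSet(**COV),
                          doses=(DoseEvent(24.0, 200.0, "oral"),),
                          observations=(Observation(12.0, 1.0),))

    def test_covariate_value_lookup(self):
        cov = CovariateSet(**{**COV, "SEX": "female", "phenotype": "PM"})
        assert cov.value("SEX") == 1.0
        assert cov.value("PM") == 1.0
        assert cov.value("IM") == 0.0
        assert cov.value("CRP") == 59.0


class TestDatasetIO:
    def test_minimal_two_row_file(self, tmp_path):
        p = tmp_path / "mini.csv"
        p.write_text(
            "ID,TIME,AMT,DUR,ROUTE,DV,MDV,AGE,WT,SEX,ALB,CRP,CYP2C19\n"
            "P1,0,200,2,intravenous,,1,70,65,M,34.8,59,NM\n"
            "P1,120,0,0,,4.2,0,70,65,M,34.8,59,NM\n")
        subs = read_dataset(p)
        assert len(subs) == 1
        (s,) = subs
        assert len(s.doses) == 1 and len(s.observations) == 1
        assert s.observations[0].concentration == 4.2
        assert s.covariates.SEX == "male"

    def test_bql_row_retained_and_flagged(self, tmp_path):
        p = tmp_path / "bql.csv"
        p.write_text(
            "ID,TIME,AMT,DUR,ROUTE,DV,MDV,AGE,WT,SEX,ALB,CRP,CYP2C19\n"
            "P1,0,200,2,intravenous,,1,70,65,M,34.8,59,NM\n"
            "P1,120,0,0,,0.05,0,70,65,M,34.8,59,NM\n")
        (s,) = read_dataset(p)
        assert s.observations[0].bql_flag is True

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ID,TIME,AMT,ROUTE,DV,MDV,AGE,WT,SEX,ALB,CYP2C19\n")
        with pytest.raises(SchemaError, match="CRP"):
            read_dataset(p)

    def test_negative_amount_reports_row(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text(
            "ID,TIME,AMT,DUR,ROUTE,DV,MDV,AGE,WT,SEX,ALB,CRP,CYP2C19\n"
            "P1,0,-200,2,intravenous,,1,70,65,M,34.8,59,NM\n")
        with pytest.raises(ValidationError, match="row 0"):
            read_dataset(p)

    def test_empty_cohort_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_dataset([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("ID,")

    def test_round_trip_cohort(self, tmp_path, study_cohort):
        """Write/read of a full synthetic cohort is lossless at the
        declared float precision."""
        p = tmp_path / "cohort.csv"
        write_dataset(study_cohort, p)
        back = read_dataset(p)
        assert len(back) == len(study_cohort)
        for a, b in zip(study_cohort, back):
            assert a.id == b.id
            assert a.covariates.phenotype == b.covariates.phenotype
            assert a.covariates.AGE == pytest.approx(b.covariates.AGE,
                                                     rel=1e-9)
            assert a.covariates.CRP == pytest.approx(b.covariates.CRP,
                                                     rel=1e-9)
            assert len(a.doses) == len(b.doses)
            for da, db in zip(a.doses, b.doses):
                assert (da.time, da.amount, da.route, da.n_doses) == \
                    (db.time, db.amount, db.route, db.n_doses)
                assert da.infusion_duration == pytest.approx(
                    db.infusion_duration, rel=1e-9)
            assert [o.concentration for o in a.observations] == pytest.approx(
                [o.concentration for o in b.observations], rel=1e-9)
            assert [o.bql_flag for o in a.observations] == \
                [o.bql_flag for o in b.observations]

    def test_write_is_byte_stable(self, tmp_path, small_cohort):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(small_cohort, p1)
        write_dataset(small_cohort, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_dialect_renames_columns(self, tmp_path):
        s = make_subject()
        p = tmp_path / "dialect.csv"
        dialect = {"ID": "subject", "DV": "conc"}
        write_dataset([s], p, dialect=dialect)
        header = p.read_text().splitlines()[0].split(",")
        assert "subject" in header and "conc" in header and "ID" not in header
        back = read_dataset(p, dialect=dialect)
        assert back[0].id == "S1"


class TestM1:
    def test_no_bql_is_identity(self):
        subs = [make_subject()]
        assert apply_m1(subs) == subs

    def test_counts_and_preserves_non_bql(self):
        s = SubjectRecord(
            id="S1", covariates=CovariateSet(**COV),
            doses=(DoseEvent(0.0, 200.0, "intravenous", 2.0, interval=12.0,
                             n_doses=20),),
            observations=tuple(
                Observation(t, c) for t, c in
                zip(np.arange(12.0, 132.0, 12.0),
                    [4.1, 0.05, 3.2, 2.8, 0.01, 5.0, 4.4, 3.9, 2.2, 1.1])))
        (out,) = apply_m1([s])
        assert len(out.observations) == 8
        assert [o.concentration for o in out.observations] == \
            [4.1, 3.2, 2.8, 5.0, 4.4, 3.9, 2.2, 1.1]
        assert [o.time for o in out.observations] == \
            sorted(o.time for o in out.observations)

    def test_subject_with_only_bql_dropped(self):
        s_bql = SubjectRecord(
            id="S2", covariates=CovariateSet(**COV),
            doses=(DoseEvent(0.0, 200.0, "oral"),),
            observations=(Observation(12.0, 0.02),))
        out = apply_m1([make_subject(), s_bql])
        assert [s.id for s in out] == ["S1"]

    def test_generated_cohort_bql_fraction_small(self, study_cohort):
        """Under the generator defaults the BQL fraction stays below 5%."""
        obs = [o for s in study_cohort for o in s.observations]
        frac = np.mean([o.bql_flag for o in obs])
        assert frac < 0.05
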