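import dataclasses

import numpy as np
import pytest
from scipy import stats

from sf6dbayes import cohort
from sf6dbayes.cohort import (
    CohortConfig,
    CohortConfigError,
    Respondent,
    SurveyDataset,
    ValuationRecord,
    apply_exclusions,
    generate_survey,
    read_valuations,
    response_rate_percent,
    select_design_states,
    write_valuations,
)
from sf6dbayes.state_space import PITS, dummy_matrix, parse_state


class TestDesignSelection:
    def test_study_design_size_and_pits(self):
        design = select_design_states(49, 200, seed=1)
        codes = [s.code for s in design]
        assert len(codes) == 249 and len(set(codes)) == 249
        assert PITS in codes

    def test_orthogonal_part_covers_every_level(self):
        design = select_design_states(49, 0, seed=2)
        # drop pits (possibly swapped in) before the coverage check: with 49
        # balanced rows each level appears ~8 times, so one swap cannot
        # empty a level
        cover = dummy_matrix(design).sum(axis=0)
        assert (cover > 0).all()

    def test_zero_counts_give_just_pits(self):
        assert [s.code for s in select_design_states(0, 0, seed=0)] == [PITS]

    def test_deterministic_given_seed(self):
        a = select_design_states(49, 200, seed=7)
        b = select_design_states(49, 200, seed=7)
        assert [s.code for s in a] == [s.code for s in b]

    def test_infeasible_counts_rejected(self):
        with pytest.raises(CohortConfigError):
            select_design_states(3, 0, seed=0)  # cannot cover 6 PF levels
        with pytest.raises(CohortConfigError):
            select_design_states(49, 20_000, seed=0)


class TestGenerator:
    def test_replica_provenance(self, replica_analysed):
        prov = replica_analysed.provenance
        assert prov["recruited"] == 836
        assert prov["excluded_failed_pits"] == 130
        assert prov["excluded_missing_two_plus"] == 9
        assert prov["excluded_constant"] == 86
        assert prov["retained"] == 611
        assert prov["valuations_issued"] == 3666
        assert prov["missing_among_retained"] == 148
        assert prov["analysed_valuations"] == 3518

    def test_provenance_conservation(self, replica_analysed):
        prov = replica_analysed.provenance
        assert prov["retained"] == prov["recruited"] - (
            prov["excluded_failed_pits"]
            + prov["excluded_missing_two_plus"]
            + prov["excluded_constant"]
        )
        assert (
            prov["analysed_valuations"]
            == 6 * prov["retained"] - prov["missing_among_retained"]
        )

    def test_flagged_respondents_are_exactly_those_removed(self, replica_raw):
        analysed = apply_exclusions(replica_raw)
        kept = {r.id for r in analysed.respondents}
        flagged = {r.id for r in replica_raw.respondents if r.flag is not None}
        assert kept.isdisjoint(flagged)
        assert kept | flagged == {r.id for r in replica_raw.respondents}

    def test_noise_free_limit_reproduces_linear_predictor(self):
        config = CohortConfig(
            n_recruited=20,
            n_orthogonal=10,
            n_random=30,
            n_failed_pits=0,
            n_missing_two_plus=0,
            n_constant=0,
            n_missing=0,
            sigma_u=0.0,
            sigma_e=0.0,
            truncate=False,
            seed=4,
        )
        ds = generate_survey(config)
        for rec in ds.records:
            assert rec.value == pytest.approx(
                cohort._state_mean_utility(rec.state, config), abs=1e-12
            )

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_recruited=60, n_orthogonal=10, n_random=40,
                           n_failed_pits=5, n_missing_two_plus=1, n_constant=3,
                           n_missing=6, seed=9)
        paths = []
        for name in ("a.csv", "b.csv"):
            ds = generate_survey(dataclasses.replace(cfg))
            p = tmp_path / name
            write_valuations(ds, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_value_distribution_character(self, replica_analysed):
        vals = replica_analysed.observed_values()
        assert vals.min() >= -1.0 and vals.max() <= 1.0
        # worse-than-death values are a small minority
        assert (vals < 0).mean() < 0.15
        assert stats.skew(vals) < 0
        by_state = {}
        for rec in replica_analysed.records:
            by_state.setdefault(rec.state.code, []).append(rec.value)
        means = np.array([np.mean(v) for v in by_state.values()])
        assert means.min() < 0.4 and means.max() > 0.9

    def test_infeasible_configs_rejected(self):
        with pytest.raises(CohortConfigError):
            CohortConfig(n_failed_pits=900).validate()
        with pytest.raises(CohortConfigError):
            CohortConfig(n_missing=700).validate()
        with pytest.raises(CohortConfigError):
            CohortConfig(sigma_e=-0.1).validate()


def _mini_dataset(values, pits_value=0.3):
    resp = Respondent(id="R1")
    states = ["123111", "211111", "111211", "111121", "111112"]
    records = [
        ValuationRecord("R1", parse_state(c), v, pos)
        for pos, (c, v) in enumerate(zip(states, values), start=1)
    ]
    records.append(ValuationRecord("R1", parse_state(PITS), pits_value, 6))
    return SurveyDataset([resp], records, [r.state for r in records])


class TestExclusions:
    def test_clean_dataset_unchanged(self):
        ds = _mini_dataset([0.9, 0.8, 0.7, 0.6, 0.5])
        out = apply_exclusions(ds)
        assert out.provenance["retained"] == 1
        assert len(out.records) == 6

    def test_constant_five_values_excluded(self):
        out = apply_exclusions(_mini_dataset([0.5] * 5))
        assert out.provenance["excluded_constant"] == 1
        assert out.provenance["retained"] == 0

    def test_missing_pits_excluded_first(self):
        out = apply_exclusions(_mini_dataset([0.5] * 5, pits_value=None))
        assert out.provenance["excluded_failed_pits"] == 1
        assert out.provenance["excluded_constant"] == 0

    def test_two_missing_excluded(self):
        out = apply_exclusions(_mini_dataset([None, None, 0.7, 0.6, 0.5]))
        assert out.provenance["excluded_missing_two_plus"] == 1

    def test_single_missing_dropped_not_excluded(self):
        out = apply_exclusions(_mini_dataset([None, 0.8, 0.7, 0.6, 0.5]))
        assert out.provenance["retained"] == 1
        assert out.provenance["missing_among_retained"] == 1
        assert len(out.records) == 5


class TestIO:
    def test_csv_roundtrip_lossless(self, tmp_path):
        cfg = CohortConfig(n_recruited=30, n_orthogonal=8, n_random=20,
                           n_failed_pits=2, n_missing_two_plus=1, n_constant=2,
                           n_missing=3, seed=13)
        ds = generate_survey(cfg)
        path = tmp_path / "vals.csv"
        write_valuations(ds, path)
        back = read_valuations(path)
        assert len(back.records) == len(ds.records)
        for a, b in zip(ds.records, back.records):
            assert (a.respondent_id, a.state.code, a.position) == (
                b.respondent_id,
                b.state.code,
                b.position,
            )
            assert a.value == b.value  # exact, including None

    def test_out_of_range_value_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "respondent_id,state_code,position,value\nR1,111111,1,1.5\n"
        )
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            read_valuations(path)


def test_response_rate_matches_study():
    rate = response_rate_percent()
    assert rate == pytest.approx(100 * 836 / 1278)
    assert round(rate) == 65
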