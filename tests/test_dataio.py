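import io

import numpy as np
import pandas as pd
import pytest

from pkautoinit.dataio import (
    ParseError,
    annotate_doses,
    flag_steady_state,
    parse_dataset,
    pool_observations,
)


def _annotate(csv, **kw):
    return annotate_doses(parse_dataset(io.StringIO(csv)), **kw)


class TestParse:
    def test_dose_and_observation_rows(self):
        df = parse_dataset(io.StringIO(
            "ID,TIME,AMT,EVID,DV\n1,0,100,1,.\n1,2,0,0,5\n1,4,0,0,3\n"
        ))
        assert len(df) == 3
        assert (df["evid"] == 1).sum() == 1
        assert (df["evid"] == 0).sum() == 2

    def test_addl_expansion(self):
        df = parse_dataset(io.StringIO(
            "ID,TIME,AMT,EVID,ADDL,II,DV\n1,0,100,1,2,12,.\n1,30,0,0,0,0,4\n"
        ))
        doses = df[df["evid"] == 1]
        assert list(doses["time"]) == [0.0, 12.0, 24.0]
        assert (doses["amt"] == 100).all()

    def test_missing_dv_column_errors(self):
        with pytest.raises(ParseError, match="DV"):
            parse_dataset(io.StringIO("ID,TIME,AMT\n1,0,100\n"))

    def test_negative_time_errors(self):
        with pytest.raises(ParseError, match="negative TIME"):
            parse_dataset(io.StringIO("ID,TIME,AMT,EVID,DV\n1,-1,100,1,.\n"))

    def test_headers_case_insensitive(self):
        df = parse_dataset(io.StringIO("id,Time,amt,evid,dv\n1,0,100,1,.\n1,1,0,0,2\n"))
        assert set(df.columns) >= {"id", "time", "amt", "dv"}


class TestAnnotate:
    def test_single_dose_tad_and_occasion(self):
        _, obs = _annotate("ID,TIME,AMT,EVID,DV\n1,0,100,1,.\n1,2,0,0,5\n")
        assert obs.loc[0, "tad"] == 2.0
        assert obs.loc[0, "occasion"] == "first_dose"
        assert not obs.loc[0, "at_steady_state"]

    def test_five_identical_doses_reach_steady_state(self):
        rows = ["ID,TIME,AMT,EVID,DV"]
        rows += [f"1,{12*k},100,1,." for k in range(6)]
        rows += ["1,62,0,0,4"]
        _, obs = _annotate("\n".join(rows) + "\n")
        assert obs.loc[0, "at_steady_state"]
        assert obs.loc[0, "occasion"] == "multi_dose"

    def test_irregular_intervals_are_not_steady_state(self):
        # doses at 0, 12, 30 h: interval deviation > 25% and < 5 doses
        rows = ["ID,TIME,AMT,EVID,DV", "1,0,100,1,.", "1,12,100,1,.",
                "1,30,100,1,.", "1,32,0,0,4"]
        _, obs = _annotate("\n".join(rows) + "\n")
        assert not obs.loc[0, "at_steady_state"]

    def test_five_half_lives_rule_with_lazy_t_half(self):
        rows = ["ID,TIME,AMT,EVID,DV"] + [f"1,{24*k},100,1,." for k in range(3)]
        rows += ["1,50,0,0,4"]
        doses, obs = _annotate("\n".join(rows) + "\n")
        assert not obs.loc[0, "at_steady_state"]  # 3 doses, no half-life yet
        obs2 = flag_steady_state(obs, doses, t_half=8.0)  # 48 h >= 5*8 h
        assert obs2.loc[0, "at_steady_state"]

    def test_predose_observation_excluded(self):
        with pytest.warns(UserWarning, match="before the first dose"):
            _, obs = _annotate(
                "ID,TIME,AMT,EVID,DV\n1,0,0,0,3\n1,1,100,1,.\n1,2,0,0,5\n"
            )
        assert len(obs) == 1

    def test_subject_without_dose_dropped(self):
        with pytest.warns(UserWarning, match="no dose"):
            _, obs = _annotate(
                "ID,TIME,AMT,EVID,DV\n1,0,100,1,.\n1,2,0,0,5\n2,1,0,0,3\n"
            )
        assert set(obs["id"]) == {1}

    def test_oral_route_detected_from_depot_cmt(self):
        _, obs = _annotate(
            "ID,TIME,AMT,EVID,CMT,DV\n1,0,100,1,1,.\n1,2,0,0,2,5\n"
        )
        assert obs.loc[0, "route"] == "extravascular"

    def test_infusion_route_detected_from_rate(self):
        _, obs = _annotate(
            "ID,TIME,AMT,RATE,EVID,DV\n1,0,100,50,1,.\n1,3,0,0,0,5\n"
        )
        assert obs.loc[0, "route"] == "infusion"


def _obs_frame(tads, dvs, dose=100.0):
    n = len(tads)
    return pd.DataFrame({
        "id": np.arange(n), "time": tads, "dv": dvs, "tad": tads,
        "dose_amount": dose, "dose_number": 1, "route": "bolus",
        "occasion": "first_dose", "at_steady_state": False, "tau": np.nan,
    })


class TestPooling:
    def test_twenty_unique_tads_make_ten_bins_of_two(self):
        tads = np.arange(1.0, 21.0)
        prof = pool_observations(_obs_frame(tads, np.ones(20)), "mixed", 10)
        assert len(prof) == 10
        assert (prof.n_points == 2).all()

    def test_fewer_unique_tads_shrink_bin_count(self):
        tads = np.array([1.0, 2, 3, 4, 5])
        prof = pool_observations(_obs_frame(tads, np.ones(5)), "mixed", 10)
        assert len(prof) == 5

    def test_bin_representative_is_median_pair(self):
        prof = pool_observations(
            _obs_frame([2.0, 2.5], [8.0, 6.0], dose=1.0), "mixed", 1
        )
        assert prof.tad[0] == pytest.approx(2.25)
        assert prof.conc[0] == pytest.approx(7.0)

    def test_pooling_idempotent_on_single_point_bins(self):
        tads = np.array([1.0, 3, 7, 12])
        dvs = np.array([9.0, 6, 3, 1])
        prof = pool_observations(_obs_frame(tads, dvs, dose=1.0), "mixed", 10)
        np.testing.assert_allclose(prof.tad, tads)
        np.testing.assert_allclose(prof.conc, dvs)

    def test_dose_normalization_scale_invariance(self):
        tads = np.linspace(1, 12, 8)
        dvs = 10 * np.exp(-0.2 * tads)
        a = pool_observations(_obs_frame(tads, dvs, dose=100.0), "mixed", 4)
        b = pool_observations(_obs_frame(tads, 5 * dvs, dose=500.0), "mixed", 4)
        np.testing.assert_allclose(a.conc, b.conc)

    def test_observation_count_conserved(self):
        rng = np.random.default_rng(0)
        tads = rng.choice(np.arange(1, 15, dtype=float), size=40)
        prof = pool_observations(_obs_frame(tads, np.ones(40)), "mixed", 6)
        assert prof.n_points.sum() == 40

    def test_empty_group_gives_empty_profile(self):
        prof = pool_observations(
            _obs_frame([1.0], [1.0]), "multi_dose", 10
        )
        assert prof.is_empty
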