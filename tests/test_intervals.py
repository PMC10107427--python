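"""Interval construction: censoring rules, cutoff, and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from camprox.intervals import AnalysisSpec, accounting, build_intervals

from conftest import EPOCH, brute_force_intervals, make_dep, make_obs

AVOID = AnalysisSpec.predator_avoidance()
TRACK = AnalysisSpec.prey_tracking()


def run_stream(rows, roles, end_h, spec, cause="pickup"):
    obs = make_obs(rows, roles)
    dep = make_dep([("L1", 0, end_h, cause)])
    return build_intervals(obs, dep, spec)


def test_single_predator_prey_pair_is_event(roles):
    ints, _ = run_stream([(0, "ocelot"), (4, "agouti")], roles, 100, AVOID)
    assert len(ints) == 1
    row = ints.iloc[0]
    assert row["duration_h"] == pytest.approx(4.0)
    assert row["outcome"] == "event"
    assert row["closing_species"] == "agouti"


def test_nontarget_interrupts_as_competing_censor(roles):
    ints, _ = run_stream(
        [(0, "ocelot"), (2, "human"), (4, "agouti")], roles, 100, AVOID
    )
    assert len(ints) == 1
    row = ints.iloc[0]
    assert row["duration_h"] == pytest.approx(2.0)
    assert row["outcome"] == "censored_competing"
    assert row["closing_species"] == "human"


def test_tracking_without_competing_prey_opens_overlapping_intervals(roles):
    """agouti@0 and paca@5 both wait for the ocelot@10; intervening prey is skipped."""
    ints, _ = run_stream(
        [(0, "agouti"), (5, "paca"), (10, "ocelot")], roles, 100, TRACK
    )
    assert sorted(ints["duration_h"]) == pytest.approx([5.0, 10.0])
    assert set(ints["outcome"]) == {"event"}
    assert set(ints["closing_species"]) == {"ocelot"}


def test_camera_failure_censors_at_deployment_end(roles):
    ints, _ = run_stream([(0, "agouti")], roles, 50, TRACK, cause="failure")
    row = ints.iloc[0]
    assert row["duration_h"] == pytest.approx(50.0)
    assert row["outcome"] == "censored_camera"
    assert row["closing_species"] is None


def test_interval_over_cutoff_omitted_and_counted(roles):
    ints, summary = run_stream([(0, "ocelot"), (80, "agouti")], roles, 100, AVOID)
    assert len(ints) == 0
    assert summary["omitted_over_cutoff"] == 1


def test_pooled_accounting_of_the_five_streams(roles):
    """Hand-enumerated pooled outcomes of the five canonical streams."""
    runs = [
        ([(0, "ocelot"), (4, "agouti")], 100, AVOID, "pickup"),
        ([(0, "ocelot"), (2, "human"), (4, "agouti")], 100, AVOID, "pickup"),
        ([(0, "agouti"), (5, "paca"), (10, "ocelot")], 100, TRACK, "pickup"),
        ([(0, "agouti")], 50, TRACK, "failure"),
        ([(0, "ocelot"), (80, "agouti")], 100, AVOID, "pickup"),
    ]
    pooled = {"event": 0, "censored_competing": 0, "censored_camera": 0, "omitted": 0}
    for rows, end, spec, cause in runs:
        ints, summary = run_stream(rows, roles, end, spec, cause=cause)
        for k in ("event", "censored_competing", "censored_camera"):
            pooled[k] += summary[k]
        pooled["omitted"] += (
            summary["omitted_over_cutoff"] + summary["omitted_zero_duration"]
        )
    assert pooled == {
        "event": 3,
        "censored_competing": 1,
        "censored_camera": 1,
        "omitted": 1,
    }


def test_second_predator_censors_open_avoidance_interval(roles):
    ints, _ = run_stream(
        [(0, "ocelot"), (3, "ocelot"), (6, "agouti")], roles, 100, AVOID
    )
    assert list(ints["outcome"]) == ["censored_competing", "event"]
    assert ints["duration_h"].tolist() == pytest.approx([3.0, 3.0])


def test_initiator_at_deployment_end_is_zero_duration(roles):
    ints, summary = run_stream([(100, "agouti")], roles, 100, TRACK)
    assert len(ints) == 0
    assert summary["omitted_zero_duration"] == 1


def test_intervals_never_span_deployments(roles):
    """A pickup/redeploy boundary censors exactly like a failure."""
    obs = make_obs([(10, "ocelot"), (60, "agouti")], roles)
    dep = make_dep([("L1", 0, 48, "pickup"), ("L1", 48, 100, "pickup")])
    ints, _ = build_intervals(obs, dep, AVOID)
    row = ints.iloc[0]
    assert row["outcome"] == "censored_camera"
    assert row["duration_h"] == pytest.approx(38.0)


def test_unsorted_observations_rejected(roles):
    obs = make_obs([(5, "ocelot"), (1, "agouti")], roles)
    obs = obs.iloc[::-1].reset_index(drop=True)  # break the sort
    dep = make_dep([("L1", 0, 100)])
    with pytest.raises(ValueError, match="sorted"):
        build_intervals(obs, dep, AVOID)


def test_accounting_identity_and_empty_table(roles):
    ints, summary = run_stream(
        [(0, "ocelot"), (4, "agouti"), (10, "ocelot"), (90, "agouti")],
        roles,
        120,
        AVOID,
    )
    table = accounting(ints, summary)
    assert table["stored"] + table["omitted_over_cutoff"] + table[
        "omitted_zero_duration"
    ] == table["n_initiators"]
    empty, esum = run_stream([(0, "agouti")], roles, 100, AVOID)
    etable = accounting(empty, esum)
    assert etable["stored"] == 0 and etable["n_initiators"] == 0


def _random_stream(rng, n):
    species = ["ocelot", "agouti", "paca", "human", "iguana"]
    t = np.sort(rng.uniform(0, 200, size=n))
    return [(float(ti), species[rng.integers(len(species))]) for ti in t]


@pytest.mark.parametrize("spec", [AVOID, TRACK,
                                  AnalysisSpec.prey_tracking("t2", compete_prey=True),
                                  AnalysisSpec.predator_avoidance("a7", 168.0)])
def test_oracle_equivalence_on_random_streams(roles, spec):
    """build_intervals matches an independent brute-force scan record-for-record."""
    rng = np.random.default_rng(42)
    for _ in range(120):
        n = int(rng.integers(1, 13))
        rows = _random_stream(rng, n)
        end_h = float(max(t for t, _ in rows)) + float(rng.uniform(0, 100))
        ints, summary = run_stream(rows, roles, end_h, spec)
        stream = [(t, sp, roles.role_of(sp)) for t, sp in rows]
        expected, n_over, n_zero = brute_force_intervals(stream, end_h, spec)
        assert summary["omitted_over_cutoff"] == n_over
        assert summary["omitted_zero_duration"] == n_zero
        assert list(zip(ints["outcome"], ints["closing_species"])) == [
            (o, c) for _, _, o, c in expected
        ]
        np.testing.assert_allclose(
            ints["duration_h"].to_numpy(), [d for _, d, _, _ in expected], atol=1e-6
        )


def test_monotone_censoring_and_cutoff(roles):
    """Enlarging competing roles never adds events; raising the cutoff never drops intervals."""
    rng = np.random.default_rng(7)
    rows = _random_stream(rng, 12)
    end_h = 250.0
    small = AnalysisSpec.prey_tracking("nc", compete_prey=False)
    large = AnalysisSpec.prey_tracking("wc", compete_prey=True)
    _, s_small = run_stream(rows, roles, end_h, small)
    _, s_large = run_stream(rows, roles, end_h, large)
    assert s_large["event"] <= s_small["event"]
    assert s_large["n_initiators"] == s_small["n_initiators"]
    ints72, _ = run_stream(rows, roles, end_h, AnalysisSpec.predator_avoidance("a", 72.0))
    ints168, _ = run_stream(rows, roles, end_h, AnalysisSpec.predator_avoidance("b", 168.0))
    assert len(ints168) >= len(ints72)
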