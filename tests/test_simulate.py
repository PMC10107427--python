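"""Community simulator: diel kernels, thinning correctness, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from camprox.intervals import assign_deployments
from camprox.simulate import (
    InteractionSpec,
    SimConfig,
    SpeciesSpec,
    bci_like_config,
    diel_intensity,
    planted_effect_summary,
    simulate_community,
)


def flat(name="agouti", role="prey", rate=5.0):
    return SpeciesSpec(name, role, rate, diel=((12.0, 0.0, 1.0),))


def one_loc_config(species, days=100.0, interactions=(), seed=0, **kw):
    return SimConfig(
        n_locations=1,
        session_days=days,
        n_sessions=1,
        failure_prob=0.0,
        species=tuple(species),
        interactions=tuple(interactions),
        seed=seed,
        **kw,
    )


def test_diel_uniform_concentration_zero():
    s = flat()
    tod = np.linspace(0, 24, 97)
    np.testing.assert_allclose(diel_intensity(s, tod), 1.0)


def test_diel_unimodal_and_symmetric():
    night = SpeciesSpec("x", "prey", 1.0, diel=((2.0, 4.0, 1.0),))
    assert diel_intensity(night, 2.0) > diel_intensity(night, 14.0)
    twin = SpeciesSpec("y", "prey", 1.0, diel=((6.0, 2.0, 0.5), (18.0, 2.0, 0.5)))
    assert diel_intensity(twin, 6.0) == pytest.approx(diel_intensity(twin, 18.0))


@pytest.mark.parametrize(
    "spec",
    [
        flat(),
        SpeciesSpec("n", "prey", 1.0, diel=((2.0, 3.0, 1.0),)),
        SpeciesSpec("m", "prey", 1.0, diel=((8.0, 2.0, 0.4), (20.0, 5.0, 0.6))),
    ],
)
def test_diel_multiplier_averages_to_one(spec):
    grid = (np.arange(4096) + 0.5) * (24.0 / 4096)
    assert diel_intensity(spec, grid).mean() == pytest.approx(1.0, abs=1e-9)


def test_invalid_species_rejected_before_simulation():
    with pytest.raises(ValueError, match="weights"):
        SpeciesSpec("x", "prey", 1.0, diel=((2.0, 1.0, 0.5),))
    with pytest.raises(ValueError, match="nonnegative"):
        SpeciesSpec("x", "prey", -1.0)
    with pytest.raises(ValueError, match="role"):
        SpeciesSpec("x", "wolf", 1.0)


def test_poisson_count_for_flat_single_species():
    """base_rate 5/day over 100 days: count within 3 sd of 500."""
    obs, dep, _ = simulate_community(one_loc_config([flat(rate=5.0)], seed=42))
    assert abs(len(obs) - 500) < 3 * np.sqrt(500)


def test_zero_rates_give_empty_observations_but_deployments():
    obs, dep, _ = simulate_community(one_loc_config([flat(rate=0.0)]))
    assert len(obs) == 0
    assert len(dep) == 1


def test_identical_seed_identical_tables(tmp_path):
    cfg = bci_like_config(seed=5, n_sessions=1)
    a_obs, a_dep, _ = simulate_community(cfg)
    b_obs, b_dep, _ = simulate_community(cfg)
    from camprox.io import write_deployments, write_observations

    for df, name, writer in [
        (a_obs, "a_obs.csv", write_observations),
        (b_obs, "b_obs.csv", write_observations),
        (a_dep, "a_dep.csv", write_deployments),
        (b_dep, "b_dep.csv", write_deployments),
    ]:
        writer(df, tmp_path / name)
    assert (tmp_path / "a_obs.csv").read_bytes() == (tmp_path / "b_obs.csv").read_bytes()
    assert (tmp_path / "a_dep.csv").read_bytes() == (tmp_path / "b_dep.csv").read_bytes()


def test_interevent_gaps_exponential_under_flat_null():
    """KS non-rejection at alpha=0.01 for gaps of a flat 1-species process."""
    days = 5000.0 / (3.0 / 24.0) / 24.0  # enough span for ~5000 events at 3/day
    obs, _, _ = simulate_community(one_loc_config([flat(rate=3.0)], days=days, seed=8))
    t = obs["timestamp"].astype("int64").to_numpy() / 3.6e12
    gaps = np.diff(t)
    assert gaps.size > 4000
    res = stats.kstest(gaps, "expon", args=(0, 24.0 / 3.0))
    assert res.pvalue > 0.01


def test_all_observations_inside_deployments_with_failures():
    cfg = bci_like_config(seed=11, n_sessions=2)
    obs, dep, _ = simulate_community(cfg)
    assign_deployments(obs, dep)  # raises if any observation is uncovered
    assert set(dep["end_cause"]) == {"pickup", "failure"}
    # failure sessions are truncated: end before the scheduled 90-day pickup
    fail = dep[dep["end_cause"] == "failure"]
    spans = (fail["end"] - fail["start"]).dt.total_seconds() / 86400.0
    assert (spans < 90.0).all()
    # recorded failure ends sit on the 12-h time-lapse grid
    rel_h = (fail["end"] - fail["start"]).dt.total_seconds() / 3600.0
    assert np.allclose(rel_h % 12.0, 0.0)


def test_planted_step_suppression_total():
    """theta=0 removes every responder event inside the windows."""
    inter = InteractionSpec("predator", "prey", theta=0.0, window_h=12.0)
    cfg = one_loc_config(
        [flat("ocelot", "predator", 0.5), flat("agouti", "prey", 3.0)],
        days=200.0,
        interactions=[inter],
        seed=2,
    )
    obs, dep, truth = simulate_community(cfg)
    rec = planted_effect_summary(obs, dep, truth)[0]
    assert rec["events_inside"] == 0
    assert rec["events_outside"] > 0


def test_planted_effect_ratio_estimates_theta():
    """theta=0.5, w=12 h: inside/outside responder rate ratio lands in [0.4, 0.6]."""
    inter = InteractionSpec("predator", "prey", theta=0.5, window_h=12.0)
    ratios = []
    for seed in range(4):
        cfg = one_loc_config(
            [flat("ocelot", "predator", 0.4), flat("agouti", "prey", 3.0)],
            days=400.0,
            interactions=[inter],
            seed=seed,
        )
        obs, dep, truth = simulate_community(cfg)
        ratios.append(planted_effect_summary(obs, dep, truth)[0]["rate_ratio"])
    assert 0.4 <= np.mean(ratios) <= 0.6


def test_null_interaction_ratio_near_one():
    inter = InteractionSpec("predator", "prey", theta=1.0, window_h=12.0)
    cfg = one_loc_config(
        [flat("ocelot", "predator", 0.4), flat("agouti", "prey", 3.0)],
        days=400.0,
        interactions=[inter],
        seed=6,
    )
    obs, dep, truth = simulate_community(cfg)
    assert planted_effect_summary(obs, dep, truth)[0]["rate_ratio"] == pytest.approx(
        1.0, abs=0.25
    )


def test_no_trigger_events_flagged():
    inter = InteractionSpec("predator", "prey", theta=0.5, window_h=12.0)
    cfg = one_loc_config(
        [flat("ocelot", "predator", 0.0), flat("agouti", "prey", 2.0)],
        days=50.0,
        interactions=[inter],
    )
    obs, dep, truth = simulate_community(cfg)
    rec = planted_effect_summary(obs, dep, truth)[0]
    assert rec["rate_ratio"] is None
    assert rec["flag"] == "no trigger events"


def test_config_yaml_round_trip(tmp_path):
    import yaml

    cfg = bci_like_config(seed=3)
    p = tmp_path / "scenario.yaml"
    p.write_text(yaml.safe_dump(cfg.to_dict()))
    back = SimConfig.from_yaml(p)
    assert back == cfg
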