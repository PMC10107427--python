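"""Model/Results interface, variant presets, and pipeline orchestration."""

import json

import numpy as np
import pandas as pd
import pytest

from camprox import AnalysisSpec, RunConfig, TemporalProximity, run, variant_presets
from camprox.pipeline import EXPANDED_PREDATORS, variant_seed
from camprox.simulate import SimConfig, SpeciesSpec, simulate_community


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimConfig(
        n_locations=5,
        session_days=60.0,
        n_sessions=1,
        failure_prob=0.2,
        species=(
            SpeciesSpec("ocelot", "predator", 0.25, diel=((2.0, 1.0, 1.0),)),
            SpeciesSpec("agouti", "prey", 2.0, diel=((10.0, 1.0, 1.0),)),
            SpeciesSpec("paca", "prey", 0.3),
            SpeciesSpec("human", "nontarget", 0.05, diel=((12.0, 1.0, 1.0),)),
        ),
        seed=4,
    )
    return cfg


def test_variant_presets_enumeration():
    presets = variant_presets()
    assert len(presets) == 6
    by_name = {p.name: p for p in presets}
    a3, a7 = by_name["avoidance-3d"].analysis, by_name["avoidance-7d"].analysis
    assert a7.cutoff_hours == 168.0 and a3.cutoff_hours == 72.0
    assert (a3.initiator_role, a3.event_role, a3.competing_roles, a3.ignored_roles) == (
        a7.initiator_role,
        a7.event_role,
        a7.competing_roles,
        a7.ignored_roles,
    )
    expanded = by_name["avoidance-expanded-predators"]
    assert len(expanded.promote_to_predator) == 4
    assert set(expanded.promote_to_predator) == set(EXPANDED_PREDATORS)
    tracking = by_name["tracking-3d-nocompete"].analysis
    assert tracking.initiator_role == "prey" and tracking.event_role == "predator"
    assert "prey" in tracking.ignored_roles
    assert "prey" in by_name["tracking-3d-compete"].analysis.competing_roles


def test_model_fit_returns_complete_results(small_sim):
    obs, dep, _ = simulate_community(small_sim)
    res = TemporalProximity(obs, dep, AnalysisSpec.predator_avoidance()).fit(
        n_reps=29, seed=1
    )
    assert 0 < res.p_value <= 1
    assert res.survival_fit.converged
    assert res.accounting["stored"] == len(res.intervals)
    text = res.summary()
    assert "constant hazard" in text and "empirical p" in text
    d = res.to_dict()
    assert d["weibull"]["median_h"] == pytest.approx(res.observed_median_h)


def test_median_p_agrees_in_significance_with_hazard_p(small_sim):
    """The hazard and median statistics rank permutations consistently."""
    obs, dep, _ = simulate_community(small_sim)
    res = TemporalProximity(obs, dep, AnalysisSpec.predator_avoidance()).fit(
        n_reps=99, seed=2
    )
    assert abs(res.p_value - res.p_value_median) < 0.25


def test_pipeline_report_deterministic(tmp_path, small_sim):
    variants = [v for v in variant_presets() if v.name in ("avoidance-3d",)]
    config = RunConfig(sim=small_sim, variants=variants, n_reps=19, seed=6)
    r1 = run(config)
    r2 = run(RunConfig(sim=small_sim, variants=list(variants), n_reps=19, seed=6))
    assert r1.to_json() == r2.to_json()
    p = r1.save(tmp_path / "out")
    data = json.loads(p.read_text())
    assert data["variants"]["avoidance-3d"]["permutation"]["p_value"] > 0
    assert (tmp_path / "out" / "avoidance-3d.intervals.csv").exists()
    assert (tmp_path / "out" / "avoidance-3d.null_hazards.txt").exists()


def test_seed_isolation_across_variants(small_sim):
    """Adding a variant never changes another variant's numbers."""
    presets = {v.name: v for v in variant_presets()}
    one = RunConfig(sim=small_sim, variants=[presets["avoidance-3d"]], n_reps=19, seed=6)
    two = RunConfig(
        sim=small_sim,
        variants=[presets["avoidance-3d"], presets["tracking-3d-nocompete"]],
        n_reps=19,
        seed=6,
    )
    a = run(one).data["variants"]["avoidance-3d"]
    b = run(two).data["variants"]["avoidance-3d"]
    assert a == b
    assert variant_seed(6, "avoidance-3d") != variant_seed(6, "tracking-3d-nocompete")
    assert variant_seed(6, "avoidance-3d") != variant_seed(7, "avoidance-3d")


def test_report_contains_every_variant_even_on_failure(small_sim):
    """A variant that cannot fit appears as an explicit failure record."""
    impossible = AnalysisSpec(
        name="no-events",
        initiator_role="predator",
        event_role="prey",
        competing_roles=frozenset({"nontarget", "predator", "prey"}) - {"prey"},
        ignored_roles=frozenset(),
        cutoff_hours=0.0001,
    )
    from camprox.pipeline import VariantSpec

    config = RunConfig(
        sim=small_sim,
        variants=[VariantSpec("no-events", impossible)],
        n_reps=5,
        seed=1,
    )
    report = run(config)
    assert "error" in report.data["variants"]["no-events"]


def test_activity_gate_reports_overlap(small_sim):
    config = RunConfig(
        sim=small_sim,
        variants=[variant_presets()[0]],
        n_reps=5,
        seed=2,
        activity_n_boot=20,
    )
    act = run(config).data["activity"]
    assert act["evaluated"]
    assert 0.0 <= act["overlap_coefficient"] <= 1.0


def test_run_config_yaml_and_from_csv(tmp_path, small_sim, roles):
    """File-based round trip through the CLI-facing configuration."""
    import yaml

    from camprox.io import write_deployments, write_observations

    obs, dep, _ = simulate_community(small_sim)
    write_observations(obs, tmp_path / "observations.csv")
    write_deployments(dep, tmp_path / "deployments.csv")
    cfg = {
        "data": {
            "observations": str(tmp_path / "observations.csv"),
            "deployments": str(tmp_path / "deployments.csv"),
        },
        "roles": {
            "predator": ["ocelot"],
            "prey": ["agouti", "paca"],
            "nontarget": ["human"],
        },
        "variants": ["avoidance-3d"],
        "n_reps": 9,
        "seed": 3,
    }
    p = tmp_path / "run.yaml"
    p.write_text(yaml.safe_dump(cfg))
    config = RunConfig.from_yaml(p)
    report = run(config)
    v = report.data["variants"]["avoidance-3d"]
    assert v["permutation"]["n_reps"] == 9
    # and the Model can be built straight from the same files
    from camprox.io import RoleConfig

    model = TemporalProximity.from_csv(
        tmp_path / "observations.csv",
        tmp_path / "deployments.csv",
        RoleConfig(
            predator_species={"ocelot"},
            prey_species={"agouti", "paca"},
            nontarget_species={"human"},
        ),
    )
    assert len(model.observations) == len(obs)
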