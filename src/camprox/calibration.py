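"""Self-calibration harnesses: Type-I error and power of the permutation test.

These run the full pipeline (simulate -> intervals -> Weibull -> permutation)
many times on a small desk-scale community to measure the test's operating
characteristics: the false-rejection rate under a null community with no
planted interaction, and the rejection rate as a function of the planted
effect size theta for both hypotheses.

The calibration community is deliberately smaller than the default bci-like
scenario (10 cameras, 60-day sessions, a predator at 0.2 passages/day) so
that hundreds of independent replicates are affordable; the predator is made
less rare than in the headline scenario purely to keep the number of
avoidance intervals per replicate (~120) in a regime where the Weibull fit is
stable on every permutation replicate.
"""

from __future__ import annotations

import numpy as np

from .intervals import AnalysisSpec
from .io import ROLE_NONTARGET, ROLE_PREDATOR, ROLE_PREY
from .permutation import empirical_p, null_distribution
from .simulate import InteractionSpec, SimConfig, SpeciesSpec, simulate_community

__all__ = [
    "calibration_config",
    "type1_calibration",
    "power_curve",
    "single_run_p",
]


def calibration_config(seed: int, interactions=()) -> SimConfig:
    return SimConfig(
        n_locations=10,
        session_days=60.0,
        n_sessions=1,
        failure_prob=0.1,
        species=(
            SpeciesSpec("ocelot", ROLE_PREDATOR, 0.2, diel=((2.0, 1.0, 1.0),)),
            SpeciesSpec("agouti", ROLE_PREY, 1.5, diel=((10.0, 1.0, 1.0),)),
            SpeciesSpec("paca", ROLE_PREY, 0.4, diel=((22.0, 1.0, 1.0),)),
            SpeciesSpec("human", ROLE_NONTARGET, 0.02, diel=((12.0, 1.0, 1.0),)),
        ),
        interactions=tuple(interactions),
        seed=seed,
    )


def avoidance_interaction(theta: float, window_h: float = 12.0) -> InteractionSpec:
    return InteractionSpec(ROLE_PREDATOR, ROLE_PREY, theta=theta, window_h=window_h)


def tracking_interaction(theta: float, window_h: float = 6.0) -> InteractionSpec:
    return InteractionSpec(ROLE_PREY, ROLE_PREDATOR, theta=theta, window_h=window_h)


def single_run_p(
    sim_seed: int,
    perm_seed: int,
    interactions=(),
    analysis: AnalysisSpec | None = None,
    n_reps: int = 199,
) -> dict:
    """One simulate-and-test replicate; returns p-values for both tails."""
    spec = analysis or AnalysisSpec.predator_avoidance()
    obs, dep, _ = simulate_community(calibration_config(sim_seed, interactions))
    res = null_distribution(obs, dep, spec, n_reps=n_reps, seed=perm_seed)
    return {
        "p_less": empirical_p(res.observed_hazard, res.null_hazards, "less"),
        "p_greater": empirical_p(res.observed_hazard, res.null_hazards, "greater"),
        "observed_hazard": res.observed_hazard,
        "observed_median": res.observed_median,
        "null_median_mean": res.null_median_mean,
        "n_failed": res.n_failed,
    }


def type1_calibration(
    n_sims: int = 200, n_reps: int = 199, seed: int = 0, alpha: float = 0.05
) -> dict:
    """False-rejection rate of both one-sided tests on null communities."""
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.spawn(1)[0].generate_state(n_sims) % (2**31)
    perm_seeds = ss.spawn(2)[1].generate_state(n_sims) % (2**31)
    reject_less = reject_greater = 0
    for i in range(n_sims):
        r = single_run_p(int(sim_seeds[i]), int(perm_seeds[i]), n_reps=n_reps)
        reject_less += r["p_less"] <= alpha
        reject_greater += r["p_greater"] <= alpha
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "rate_less": reject_less / n_sims,
        "rate_greater": reject_greater / n_sims,
    }


def power_curve(
    thetas,
    kind: str = "avoidance",
    n_sims: int = 12,
    n_reps: int = 99,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the pre-registered one-sided test per effect size.

    kind="avoidance": predator->prey suppression, direction "less";
    kind="tracking":  prey->predator attraction, direction "greater".
    """
    if kind == "avoidance":
        analysis = AnalysisSpec.predator_avoidance()
        make = avoidance_interaction
        tail = "p_less"
    elif kind == "tracking":
        analysis = AnalysisSpec.prey_tracking()
        make = tracking_interaction
        tail = "p_greater"
    else:
        raise ValueError("kind must be 'avoidance' or 'tracking'")
    ss = np.random.SeedSequence(seed + 17)
    sim_seeds = ss.spawn(1)[0].generate_state(n_sims * len(thetas)) % (2**31)
    perm_seeds = ss.spawn(2)[1].generate_state(n_sims * len(thetas)) % (2**31)
    rates, medians_obs, medians_null = [], [], []
    j = 0
    for theta in thetas:
        inter = () if theta == 1.0 else (make(theta),)
        rej = 0
        mo, mn = [], []
        for _ in range(n_sims):
            r = single_run_p(
                int(sim_seeds[j]), int(perm_seeds[j]), inter, analysis, n_reps
            )
            rej += r[tail] <= alpha
            mo.append(r["observed_median"])
            mn.append(r["null_median_mean"])
            j += 1
        rates.append(rej / n_sims)
        medians_obs.append(float(np.mean(mo)))
        medians_null.append(float(np.mean(mn)))
    return {
        "kind": kind,
        "thetas": list(thetas),
        "rejection_rates": rates,
        "mean_observed_median_h": medians_obs,
        "mean_null_median_h": medians_null,
        "n_sims": n_sims,
        "n_reps": n_reps,
        "alpha": alpha,
    }
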