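"""Shared fixtures: a tiny species-role vocabulary and compact stream builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from camprox.io import RoleConfig

EPOCH = pd.Timestamp("2020-01-01 00:00:00")


@pytest.fixture(scope="session")
def roles() -> RoleConfig:
    return RoleConfig(
        predator_species={"ocelot"},
        prey_species={"agouti", "paca", "iguana"},
        nontarget_species={"human"},
    )


def make_obs(rows, roles: RoleConfig, location="L1", epoch=EPOCH) -> pd.DataFrame:
    """Build an observation frame from (hours, species) pairs at one location."""
    recs = []
    for item in rows:
        hours, species = item[0], item[1]
        loc = item[2] if len(item) > 2 else location
        recs.append(
            {
                "location": loc,
                "timestamp": epoch + pd.Timedelta(hours=float(hours)),
                "species": species,
                "role": roles.role_of(species),
            }
        )
    obs = pd.DataFrame(
        recs, columns=["location", "timestamp", "species", "role"]
    )
    return obs.sort_values(["location", "timestamp"], kind="stable", ignore_index=True)


def make_dep(spans, epoch=EPOCH) -> pd.DataFrame:
    """Build a deployment frame from (location, start_h, end_h[, cause]) tuples."""
    recs = []
    for item in spans:
        loc, s, e = item[0], item[1], item[2]
        cause = item[3] if len(item) > 3 else "pickup"
        recs.append(
            {
                "location": loc,
                "start": epoch + pd.Timedelta(hours=float(s)),
                "end": epoch + pd.Timedelta(hours=float(e)),
                "end_cause": cause,
            }
        )
    return pd.DataFrame(recs, columns=["location", "start", "end", "end_cause"])


def brute_force_intervals(stream, dep_end_h, spec):
    """Independent per-initiator forward scan on one deployment's stream.

    *stream* is a list of (hours, species, role) in observation order.
    Returns (stored, n_over, n_zero) where stored is a list of
    (start_h, duration_h, outcome, closing_species).
    """
    stored, n_over, n_zero = [], 0, 0
    for i, (t0, _sp, role) in enumerate(stream):
        if role != spec.initiator_role:
            continue
        rec = None
        for t1, sp1, role1 in stream[i + 1 :]:
            if role1 == spec.event_role:
                rec = (t0, t1 - t0, "event", sp1)
                break
            if role1 in spec.competing_roles:
                rec = (t0, t1 - t0, "censored_competing", sp1)
                break
        if rec is None:
            rec = (t0, dep_end_h - t0, "censored_camera", None)
        if rec[1] <= 0:
            n_zero += 1
        elif rec[1] > spec.cutoff_hours:
            n_over += 1
        else:
            stored.append(rec)
    return stored, n_over, n_zero
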