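"""Time-to-event interval construction from per-location observation streams.

Each observation whose role matches the analysis's *initiator* role opens an
interval.  Scanning forward within the same deployment, the first subsequent
observation whose role is the *event* role closes it as an observed event; the
first whose role is a *competing* role closes it as right-censored
(``censored_competing``); *ignored* roles — and any role not named by the
analysis — are skipped.  If the deployment ends first (pickup or inferred
failure time), the interval is right-censored at the deployment's effective
end (``censored_camera``).  Intervals longer than the cutoff, and zero-length
intervals from simultaneous triggers, are omitted and counted, never stored.

Both censoring outcomes enter the survival likelihood identically as right
censoring; competing events are not modelled as a competing-risks likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ROLE_EXCLUDED, ROLE_NONTARGET, ROLE_PREDATOR, ROLE_PREY

logger = logging.getLogger(__name__)

__all__ = ["AnalysisSpec", "build_intervals", "accounting", "assign_deployments"]

OUTCOME_EVENT = "event"
OUTCOME_COMPETING = "censored_competing"
OUTCOME_CAMERA = "censored_camera"

_NS_PER_HOUR = 3.6e12


@dataclass(frozen=True)
class AnalysisSpec:
    """Defines one directed hypothesis as an interval-classification rule.

    ``predator_avoidance()`` opens an interval at every predator passage and
    waits for prey (longer-than-chance waits indicate avoidance);
    ``prey_tracking()`` opens one at every prey passage and waits for a
    predator (shorter-than-chance waits indicate tracking).

    ``direction`` is the tail of the permutation test on the constant hazard:
    avoidance predicts a hazard *below* the null (direction="less"), tracking
    a hazard *above* it (direction="greater").
    """

    name: str
    initiator_role: str
    event_role: str
    competing_roles: frozenset = field(default_factory=frozenset)
    ignored_roles: frozenset = field(default_factory=frozenset)
    cutoff_hours: float = 72.0
    direction: str = "less"

    def __post_init__(self):
        object.__setattr__(self, "competing_roles", frozenset(self.competing_roles))
        object.__setattr__(self, "ignored_roles", frozenset(self.ignored_roles))
        if self.event_role in self.competing_roles:
            raise ValueError("event_role cannot also be a competing role")
        if self.event_role in self.ignored_roles:
            raise ValueError("event_role cannot also be an ignored role")
        if self.cutoff_hours <= 0:
            raise ValueError("cutoff_hours must be positive")
        if self.direction not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")
        if self.cutoff_hours not in (72.0, 168.0):
            logger.info(
                "analysis %r uses a non-standard cutoff of %.1f h",
                self.name,
                self.cutoff_hours,
            )

    @classmethod
    def predator_avoidance(cls, name="avoidance", cutoff_hours=72.0) -> "AnalysisSpec":
        # A second predator before any prey interrupts (censors) the open interval.
        return cls(
            name=name,
            initiator_role=ROLE_PREDATOR,
            event_role=ROLE_PREY,
            competing_roles=frozenset({ROLE_NONTARGET, ROLE_PREDATOR}),
            ignored_roles=frozenset(),
            cutoff_hours=cutoff_hours,
            direction="less",
        )

    @classmethod
    def prey_tracking(
        cls, name="tracking", cutoff_hours=72.0, compete_prey=False
    ) -> "AnalysisSpec":
        """Prey→predator intervals.

        With ``compete_prey=False`` (the headline variant) intervening prey
        neither close nor censor an open interval, so a single predator
        passage may close several overlapping intervals; with
        ``compete_prey=True`` every later prey censors the open interval.
        """
        if compete_prey:
            competing = frozenset({ROLE_NONTARGET, ROLE_PREY})
            ignored = frozenset()
        else:
            competing = frozenset({ROLE_NONTARGET})
            ignored = frozenset({ROLE_PREY})
        return cls(
            name=name,
            initiator_role=ROLE_PREY,
            event_role=ROLE_PREDATOR,
            competing_roles=competing,
            ignored_roles=ignored,
            cutoff_hours=cutoff_hours,
            direction="greater",
        )


def assign_deployments(obs: pd.DataFrame, dep: pd.DataFrame) -> np.ndarray:
    """Map each observation to the row index of its covering deployment.

    Coverage is inclusive at both ends; an observation at a shared
    pickup/redeploy instant is assigned to the later (opening) session.
    Raises if any observation falls outside every deployment at its location.
    """
    dep_idx = np.full(len(obs), -1, dtype=np.int64)
    t_all = obs["timestamp"].to_numpy()
    loc_groups = obs.groupby("location", sort=False).indices
    dep_loc_groups = dep.groupby("location", sort=False).indices
    for loc, o_idx in loc_groups.items():
        d_idx = dep_loc_groups.get(loc)
        if d_idx is None:
            raise ValueError(f"observations at location {loc!r} with no deployment")
        d_idx = d_idx[np.argsort(dep["start"].to_numpy()[d_idx], kind="stable")]
        starts = dep["start"].to_numpy()[d_idx]
        ends = dep["end"].to_numpy()[d_idx]
        t = t_all[o_idx]
        pos = np.searchsorted(starts, t, side="right") - 1
        ok = (pos >= 0) & (t <= ends[np.clip(pos, 0, None)])
        if not ok.all():
            bad = o_idx[~ok][0]
            raise ValueError(
                f"observation outside deployment coverage: location {loc!r} "
                f"at {obs['timestamp'].iloc[bad]}"
            )
        dep_idx[o_idx] = d_idx[pos]
    return dep_idx


def _next_closer(mask: np.ndarray) -> np.ndarray:
    """Index of the first True strictly after each position (len(mask) if none)."""
    m = mask.size
    idx = np.where(mask, np.arange(m), m)
    suffix_min = np.minimum.accumulate(idx[::-1])[::-1]
    nxt = np.empty(m, dtype=np.int64)
    nxt[:-1] = suffix_min[1:]
    nxt[-1] = m
    return nxt


def build_intervals(
    obs: pd.DataFrame, dep: pd.DataFrame, spec: AnalysisSpec
) -> tuple[pd.DataFrame, dict]:
    """Build time-to-event records for one analysis.

    Returns ``(intervals, summary)`` where *intervals* has columns
    location, initiator_species, start, duration_h, outcome, closing_species
    and *summary* accounts for every initiator observation:
    stored (by outcome) + omitted_over_cutoff + omitted_zero_duration.
    """
    obs = obs[obs["role"] != ROLE_EXCLUDED].reset_index(drop=True)
    ts = obs["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    for _, idx in obs.groupby("location", sort=False).indices.items():
        if np.any(np.diff(ts[idx]) < 0):
            raise ValueError("observations not sorted by timestamp within location")

    dep_idx = assign_deployments(obs, dep)
    dep_end_ns = dep["end"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    roles = obs["role"].to_numpy()
    species_arr = obs["species"].to_numpy()
    loc_arr = obs["location"].to_numpy()
    ts_dt = obs["timestamp"].to_numpy()
    competing = sorted(spec.competing_roles)

    init_rows, dur_parts, out_parts, close_parts = [], [], [], []
    n_init = 0

    order = np.argsort(dep_idx, kind="stable")  # contiguous per deployment
    boundaries = np.flatnonzero(np.diff(dep_idx[order]) != 0) + 1
    for grp in np.split(order, boundaries):
        g_roles = roles[grp]
        init_pos = np.flatnonzero(g_roles == spec.initiator_role)
        if init_pos.size == 0:
            continue
        n_init += init_pos.size
        g_t = ts[grp]
        m = grp.size
        nxt_ev = _next_closer(g_roles == spec.event_role)
        nxt_cp = (
            _next_closer(np.isin(g_roles, competing))
            if competing
            else np.full(m, m, dtype=np.int64)
        )
        je = nxt_ev[init_pos]
        jc = nxt_cp[init_pos]
        j = np.minimum(je, jc)
        closed = j < m
        end_ns = dep_end_ns[dep_idx[grp[0]]]
        close_t = np.where(closed, g_t[np.clip(j, 0, m - 1)], end_ns)
        dur = (close_t - g_t[init_pos]) / _NS_PER_HOUR
        outcome = np.where(
            closed, np.where(je < jc, OUTCOME_EVENT, OUTCOME_COMPETING), OUTCOME_CAMERA
        )
        closing = np.where(
            closed, species_arr[grp[np.clip(j, 0, m - 1)]], None
        )
        init_rows.append(grp[init_pos])
        dur_parts.append(dur)
        out_parts.append(outcome)
        close_parts.append(closing)

    if init_rows:
        init_rows = np.concatenate(init_rows)
        dur = np.concatenate(dur_parts)
        outcome = np.concatenate(out_parts)
        closing = np.concatenate(close_parts)
    else:
        init_rows = np.empty(0, dtype=np.int64)
        dur = np.empty(0)
        outcome = np.empty(0, dtype=object)
        closing = np.empty(0, dtype=object)

    zero_mask = dur <= 0
    over_mask = (~zero_mask) & (dur > spec.cutoff_hours)
    keep = ~(zero_mask | over_mask)
    n_zero = int(zero_mask.sum())
    n_over = int(over_mask.sum())

    intervals = pd.DataFrame(
        {
            "location": pd.Series(loc_arr[init_rows[keep]], dtype=object),
            "initiator_species": pd.Series(species_arr[init_rows[keep]], dtype=object),
            "start": pd.Series(ts_dt[init_rows[keep]], dtype="datetime64[ns]"),
            "duration_h": pd.Series(dur[keep], dtype=float),
            "outcome": pd.Series(outcome[keep], dtype=object),
            "closing_species": pd.Series(closing[keep], dtype=object),
        }
    )
    out_counts = intervals["outcome"].value_counts().to_dict()
    summary = {
        "n_initiators": int(n_init),
        OUTCOME_EVENT: int(out_counts.get(OUTCOME_EVENT, 0)),
        OUTCOME_COMPETING: int(out_counts.get(OUTCOME_COMPETING, 0)),
        OUTCOME_CAMERA: int(out_counts.get(OUTCOME_CAMERA, 0)),
        "omitted_over_cutoff": int(n_over),
        "omitted_zero_duration": int(n_zero),
    }
    return intervals, summary


def accounting(intervals: pd.DataFrame, summary: dict) -> pd.Series:
    """Tabulate interval outcomes and check the conservation identity.

    Every initiator observation maps to exactly one of: a stored interval,
    an omitted over-cutoff interval, or an omitted zero-duration interval.
    """
    stored = int(len(intervals))
    table = pd.Series(
        {
            OUTCOME_EVENT: summary[OUTCOME_EVENT],
            OUTCOME_COMPETING: summary[OUTCOME_COMPETING],
            OUTCOME_CAMERA: summary[OUTCOME_CAMERA],
            "omitted_over_cutoff": summary["omitted_over_cutoff"],
            "omitted_zero_duration": summary["omitted_zero_duration"],
            "stored": stored,
            "n_initiators": summary["n_initiators"],
        },
        dtype=int,
    )
    if (
        table[OUTCOME_EVENT] + table[OUTCOME_COMPETING] + table[OUTCOME_CAMERA]
        != stored
    ):
        raise AssertionError("interval accounting mismatch: outcomes != stored")
    if (
        stored + table["omitted_over_cutoff"] + table["omitted_zero_duration"]
        != table["n_initiators"]
    ):
        raise AssertionError("interval accounting mismatch: initiators not conserved")
    return table
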