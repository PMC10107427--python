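"""Reading and writing camera-trap observation and deployment tables.

The data layout is deliberately minimal, mirroring the flat structure of a
vetted camera-trap record set: one row per independent animal passage
(location, calendar date, time of day, species) and one row per camera
deployment session (location, start, end, end cause).  Species are mapped to
analysis roles (predator / prey / nontarget / excluded) through a
:class:`RoleConfig`; role assignment is the only interpretation this module
performs — everything downstream works on roles, never on species names.

Timestamps are stored to 1-second resolution; all statistics downstream
operate in fractional hours.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoleConfig",
    "ROLE_PREDATOR",
    "ROLE_PREY",
    "ROLE_NONTARGET",
    "ROLE_EXCLUDED",
    "read_observations",
    "write_observations",
    "read_deployments",
    "write_deployments",
    "assign_roles",
    "exclusion_report",
    "independence_filter",
    "validate_coverage",
]

ROLE_PREDATOR = "predator"
ROLE_PREY = "prey"
ROLE_NONTARGET = "nontarget"
ROLE_EXCLUDED = "excluded"

OBS_COLUMNS = ["location", "timestamp", "species", "role"]
DEP_COLUMNS = ["location", "start", "end", "end_cause"]


@dataclass(frozen=True)
class RoleConfig:
    """Partition of the species vocabulary into analysis roles.

    Species absent from all three sets map to role ``excluded`` and never
    enter interval building.  The three sets must be pairwise disjoint.
    """

    predator_species: frozenset = field(default_factory=frozenset)
    prey_species: frozenset = field(default_factory=frozenset)
    nontarget_species: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        sets = [
            frozenset(self.predator_species),
            frozenset(self.prey_species),
            frozenset(self.nontarget_species),
        ]
        object.__setattr__(self, "predator_species", sets[0])
        object.__setattr__(self, "prey_species", sets[1])
        object.__setattr__(self, "nontarget_species", sets[2])
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"species assigned to more than one role: {sorted(overlap)}"
                    )

    def role_of(self, species: str) -> str:
        if species in self.predator_species:
            return ROLE_PREDATOR
        if species in self.prey_species:
            return ROLE_PREY
        if species in self.nontarget_species:
            return ROLE_NONTARGET
        return ROLE_EXCLUDED

    def with_promoted_predators(self, species) -> "RoleConfig":
        """Return a config with *species* moved into the predator role.

        Used for the expanded-predator robustness variant, where nontarget
        carnivores and humans are re-classed as predators via configuration
        alone.
        """
        promoted = frozenset(species)
        return RoleConfig(
            predator_species=self.predator_species | promoted,
            prey_species=self.prey_species - promoted,
            nontarget_species=self.nontarget_species - promoted,
        )

    @classmethod
    def from_yaml(cls, path) -> "RoleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RoleConfig":
        return cls(
            predator_species=frozenset(raw.get("predator", [])),
            prey_species=frozenset(raw.get("prey", [])),
            nontarget_species=frozenset(raw.get("nontarget", [])),
        )

    def to_dict(self) -> dict:
        return {
            "predator": sorted(self.predator_species),
            "prey": sorted(self.prey_species),
            "nontarget": sorted(self.nontarget_species),
        }


def assign_roles(observations: pd.DataFrame, role_config: RoleConfig) -> pd.DataFrame:
    """Attach a ``role`` column; unknown species become ``excluded`` with a warning."""
    obs = observations.copy()
    species = obs["species"].astype(str)
    obs["role"] = species.map(role_config.role_of)
    unknown = sorted(set(species[obs["role"] == ROLE_EXCLUDED]))
    if unknown:
        warnings.warn(
            f"species not listed in role config mapped to role=excluded: {unknown}",
            stacklevel=2,
        )
    return obs


def read_observations(path, role_config: RoleConfig, sep: str = ",") -> pd.DataFrame:
    """Read an observation table (columns location,date,time,species).

    Returns a DataFrame with columns location, timestamp, species, role,
    sorted by (location, timestamp) with input order preserved among ties.
    Unparseable timestamps are a hard error naming the offending row;
    unknown species are retained with role ``excluded`` (and a warning).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"location", "date", "time", "species"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    ts = pd.to_datetime(
        raw["date"].str.strip() + " " + raw["time"].str.strip(),
        errors="coerce",
        format="mixed",
    )
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"unparseable timestamp in row {i + 2} of {path}: "
            f"date={raw['date'].iloc[i]!r} time={raw['time'].iloc[i]!r}"
        )
    obs = pd.DataFrame(
        {
            "location": raw["location"].str.strip(),
            "timestamp": ts.dt.floor("s"),
            "species": raw["species"].str.strip(),
        }
    )
    obs = assign_roles(obs, role_config)
    return sort_observations(obs)


def sort_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (location, timestamp); simultaneous triggers keep input order."""
    return obs.sort_values(
        ["location", "timestamp"], kind="stable", ignore_index=True
    )


def write_observations(obs: pd.DataFrame, path, sep: str = ",") -> None:
    out = pd.DataFrame(
        {
            "location": obs["location"],
            "date": obs["timestamp"].dt.strftime("%Y-%m-%d"),
            "time": obs["timestamp"].dt.strftime("%H:%M:%S"),
            "species": obs["species"],
        }
    )
    out.to_csv(path, sep=sep, index=False)


def read_deployments(path, sep: str = ",") -> pd.DataFrame:
    """Read a deployment table (columns location,start,end,end_cause).

    Deployments are sorted per location; overlapping sessions at one location
    are a hard error, as are sessions with start >= end or an end cause other
    than pickup/failure.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"location", "start", "end", "end_cause"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"deployment table missing columns: {sorted(missing)}")
    dep = pd.DataFrame(
        {
            "location": raw["location"].str.strip(),
            "start": pd.to_datetime(raw["start"], format="mixed").dt.floor("s"),
            "end": pd.to_datetime(raw["end"], format="mixed").dt.floor("s"),
            "end_cause": raw["end_cause"].str.strip(),
        }
    )
    return validate_deployments(dep)


def validate_deployments(dep: pd.DataFrame) -> pd.DataFrame:
    bad_cause = set(dep["end_cause"]) - {"pickup", "failure"}
    if bad_cause:
        raise ValueError(f"unknown end_cause values: {sorted(bad_cause)}")
    if (dep["start"] >= dep["end"]).any():
        raise ValueError("deployment with start >= end")
    dep = dep.sort_values(["location", "start"], kind="stable", ignore_index=True)
    for loc, grp in dep.groupby("location", sort=False):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping deployments at location {loc!r}")
    return dep


def write_deployments(dep: pd.DataFrame, path, sep: str = ",") -> None:
    out = pd.DataFrame(
        {
            "location": dep["location"],
            "start": dep["start"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "end": dep["end"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "end_cause": dep["end_cause"],
        }
    )
    out.to_csv(path, sep=sep, index=False)


def exclusion_report(obs: pd.DataFrame) -> dict:
    """Count role=excluded records by species.

    Nontarget records are *kept* data (they censor intervals) and are never
    counted here.
    """
    excluded = obs[obs["role"] == ROLE_EXCLUDED]
    by_species = excluded["species"].value_counts().to_dict()
    return {
        "excluded": int(len(excluded)),
        "kept": int(len(obs) - len(excluded)),
        "by_species": {str(k): int(v) for k, v in sorted(by_species.items())},
    }


def independence_filter(obs: pd.DataFrame, minutes: float = 1.0) -> pd.DataFrame:
    """Drop same-species records at one location within *minutes* of the previous kept one.

    A mechanical approximation to the by-eye removal of double triggers from a
    lingering animal; off by default in the pipeline.
    """
    obs = sort_observations(obs)
    keep = np.ones(len(obs), dtype=bool)
    gap = pd.Timedelta(minutes=minutes)
    for _, idx in obs.groupby(["location", "species"], sort=False).indices.items():
        idx = np.sort(idx)
        last_kept = None
        for i in idx:
            t = obs["timestamp"].iloc[i]
            if last_kept is not None and t - last_kept <= gap:
                keep[i] = False
            else:
                last_kept = t
    return obs[keep].reset_index(drop=True)


def validate_coverage(obs: pd.DataFrame, dep: pd.DataFrame) -> None:
    """Raise if any observation lies outside every deployment at its location.

    Such records indicate a metadata bug (wrong clock, wrong session bounds)
    and are rejected rather than silently dropped.
    """
    from .intervals import assign_deployments  # shared machinery

    assign_deployments(obs, dep)  # raises on uncovered observation
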