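"""Shared fixtures: hand-built sighting tables and seeded synthetic societies."""

import numpy as np
import pandas as pd
import pytest

from podsoc.sightings import GroupByIndividual, SightingTable
from podsoc.synthetic import SocietyConfig, generate_society, simulate_sightings

ALL_CLASSES = ("very_frequent", "frequent", "low_frequent", "rare", "occasional")


def make_table(rows, time_col=False):
    """Build a SightingTable from (date, group, individual, sex, age,
    size, n_id, trammel[, time]) tuples."""
    cols = ["date", "group_id", "individual_id", "sex", "age_class",
            "group_size_observed", "n_identified", "trammel_net"]
    if time_col:
        cols.append("time")
    df = pd.DataFrame(list(rows), columns=cols)
    df["date"] = pd.to_datetime(df["date"])
    return SightingTable(df)


def uniform_probs(p=1.0):
    return {c: p for c in ALL_CLASSES}


def preference_free_config(seed, **kw):
    """Random daily grouping: no CC teams, no alliances, uniform propensity."""
    base = dict(
        seed=seed, n_individuals=20, n_days=60, n_seasons=1,
        survey_probability=1.0, groups_observed_per_day=3,
        cc_fraction=0.0, ca_fraction=0.0, n_units=1,
        within_unit_alpha=1.0, between_unit_alpha=1.0, mean_group_size=4.0,
        age_counts={"A": 20}, sex_counts={"F": 10, "M": 10},
        daily_sighting_probability=uniform_probs(0.7),
    )
    base.update(kw)
    return SocietyConfig(**base)


def planted_two_unit_config(seed, **kw):
    """Two strongly separated social units with the default CC/CA dynamics.

    The within/between propensity contrast (1.0 vs 0.05) plants the units;
    300 survey days give the association indices enough precision that
    chance alliance clustering inside a unit does not out-resolve the
    planted division.
    """
    base = dict(
        seed=seed, n_days=300, n_seasons=1, survey_probability=1.0,
        groups_observed_per_day=None, group_packing=False,
        within_unit_alpha=1.0, between_unit_alpha=0.05,
    )
    base.update(kw)
    return SocietyConfig(**base)


def lar_recovery_config(seed, **kw):
    """CC+CA+RD dynamics at the planted rates, partial daily observation."""
    base = dict(
        seed=seed, n_days=200, n_seasons=1, survey_probability=1.0,
        groups_observed_per_day=3, group_packing=False,
        n_units=1, within_unit_alpha=1.0, between_unit_alpha=1.0,
        cc_fraction=0.4, ca_fraction=0.3, ca_decay_per_day=0.3,
        age_counts={"A": 34}, sex_counts={"F": 9, "M": 12, "UN": 13},
        daily_sighting_probability=uniform_probs(1.0),
    )
    base.update(kw)
    return SocietyConfig(**base)


def random_gbi(rng, n_groups=12, n_individuals=8, n_periods=4, p=0.4):
    """Random GBI with groups spread over periods (each row non-empty)."""
    mat = (rng.random((n_groups, n_individuals)) < p).astype(np.int8)
    for r in range(n_groups):
        if mat[r].sum() == 0:
            mat[r, rng.integers(n_individuals)] = 1
    base = np.datetime64("2020-06-01", "D")
    periods = base + np.sort(rng.integers(0, n_periods, n_groups)).astype("timedelta64[D]")
    inds = tuple(f"I{k:02d}" for k in range(n_individuals))
    covs = pd.DataFrame({
        "date": periods, "group_id": [f"g{r}" for r in range(n_groups)],
        "group_size_observed": mat.sum(axis=1),
        "n_identified": mat.sum(axis=1),
        "trammel_net": False,
    })
    attrs = pd.DataFrame(
        {"sex": ["F", "M"] * (n_individuals // 2) + ["UN"] * (n_individuals % 2),
         "age_class": "A"},
        index=list(inds),
    )
    return GroupByIndividual(mat, inds, periods, covs, attrs)


@pytest.fixture(scope="session")
def default_table():
    """One simulated study at the default (study-emulating) configuration."""
    society = generate_society(SocietyConfig(seed=11))
    return society, simulate_sightings(society)
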