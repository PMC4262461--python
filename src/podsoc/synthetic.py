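"""Fission-fusion society simulator with known ground truth.

Generates photo-identification sighting tables whose social structure is
planted and therefore recoverable: social units (block-structured
association propensities), constant companions (CC: pairs that are always
grouped together), casual acquaintances (CA: team alliances that dissolve at
an exponential daily rate) and rapid disassociations (RD: one-day random
mergers).  The defaults emulate a small coastal bottlenose-dolphin
population: ~34 identifiable animals over 8 summer seasons, two overlapping
mixed-sex social units, residency from occasional to very frequent, and
roughly a hundred usable group sightings.

Mechanism per day: present animals (per-residency sighting probability)
assemble into *teams* (CC partners), teams into *atoms* via persistent
alliances (CA) and one-day mergers (RD), and atoms are optionally packed
into larger groups by propensity-weighted aggregation.  With the packing
step disabled, the all-dyad lagged association rate is, by construction,
``g(tau) = a2 + a3 * exp(-a1 * tau)`` with a2 = cc_fraction,
a3 = ca_fraction and a1 = ca_decay_per_day, which makes the temporal module
testable against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sightings import SightingTable

__all__ = ["SocietyConfig", "Society", "generate_society", "simulate_sightings"]

#: per-residency-class daily sighting probabilities (emulating site fidelity
#: from permanently resident to transient animals)
DEFAULT_SIGHTING_PROBABILITY = {
    "very_frequent": 0.90,
    "frequent": 0.60,
    "low_frequent": 0.40,
    "rare": 0.20,
    "occasional": 0.05,
}

#: residency-class head-counts for the default 34-animal population
DEFAULT_RESIDENCY_COUNTS = {
    "very_frequent": 7,
    "frequent": 7,
    "low_frequent": 5,
    "rare": 8,
    "occasional": 7,
}

DEFAULT_SEX_COUNTS = {"F": 9, "M": 12, "UN": 13}
DEFAULT_AGE_COUNTS = {"A": 20, "J": 11, "C": 3}


@dataclass
class SocietyConfig:
    """Ground-truth parameters of a simulated fission-fusion society.

    ``cc_fraction``, ``ca_fraction`` and ``ca_decay_per_day`` are the planted
    lagged-association-rate parameters (constant-companion share, casual-
    acquaintance share and its decay rate per day); their sum with the
    rapid-disassociation share is 1.  ``within_unit_alpha`` /
    ``between_unit_alpha`` weight alliance-partner choice and plant the
    community block structure.
    """

    n_individuals: int = 34
    n_units: int = 2
    unit_assignment: list | None = None
    sex_counts: dict = field(default_factory=lambda: dict(DEFAULT_SEX_COUNTS))
    age_counts: dict = field(default_factory=lambda: dict(DEFAULT_AGE_COUNTS))
    residency_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_RESIDENCY_COUNTS)
    )
    daily_sighting_probability: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGHTING_PROBABILITY)
    )
    within_unit_alpha: float = 1.0
    between_unit_alpha: float = 0.15
    cc_fraction: float = 0.4
    ca_fraction: float = 0.3
    ca_decay_per_day: float = 0.3
    mean_group_size: float = 5.0
    group_packing: bool = True
    trammel_probability: dict = field(default_factory=lambda: {0: 0.30, 1: 0.45})
    identified_fraction_range: tuple = (0.8, 1.0)
    n_days: int = 360
    n_seasons: int = 8
    season_start: str = "-06-15"
    first_year: int = 2005
    survey_probability: float = 0.20
    groups_observed_per_day: int | None = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.cc_fraction + self.ca_fraction <= 1:
            raise ValueError("cc_fraction + ca_fraction must be in [0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for p in self.daily_sighting_probability.values():
            if not 0 <= p <= 1:
                raise ValueError("sighting probabilities must be in [0, 1]")


def _allocate(counts: dict, n: int, rng) -> np.ndarray:
    """Expand a {label: count} dict to n labels, rescaling and shuffling."""
    labels = list(counts)
    raw = np.array([counts[k] for k in labels], dtype=float)
    scaled = np.floor(raw / raw.sum() * n).astype(int)
    while scaled.sum() < n:
        scaled[rng.integers(len(labels))] += 1
    out = np.repeat(labels, scaled)
    rng.shuffle(out)
    return out


@dataclass
class Society:
    """Planted ground truth: attributes, units, CC teams and propensities."""

    ids: list
    unit: np.ndarray
    sex: np.ndarray
    age_class: np.ndarray
    residency_class: np.ndarray
    team_of: np.ndarray                 # team index per individual
    propensity: np.ndarray              # true association-propensity matrix
    config: SocietyConfig

    @property
    def n_teams(self) -> int:
        return int(self.team_of.max()) + 1

    def cc_pairs(self) -> list[tuple[str, str]]:
        """Planted constant-companion (same-team) pairs."""
        pairs = []
        for t in range(self.n_teams):
            members = [self.ids[i] for i in np.flatnonzero(self.team_of == t)]
            pairs.extend(
                (members[i], members[j])
                for i in range(len(members))
                for j in range(i + 1, len(members))
            )
        return pairs

    def team_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, t in enumerate(self.team_of):
            out.setdefault(int(t), []).append(i)
        return out

    def steady_state(self) -> dict:
        """Steady-state daily counts of the alliance/merger dynamics.

        ``w_cc``: within-team (constant-companion) dyads per day;
        ``alliances`` / ``mergers``: expected numbers of persistent alliances
        and one-day mergers maintained per day, chosen so the dyad-weight
        shares match (cc_fraction, ca_fraction, 1 - cc - ca).
        """
        members = self.team_members()
        w_cc = sum(len(m) * (len(m) - 1) // 2 for m in members.values())
        f_cc, f_ca = self.config.cc_fraction, self.config.ca_fraction
        f_rd = 1.0 - f_cc - f_ca
        cross = 4.0                         # dyads created by a 2+2 team merge
        if f_cc > 0 and w_cc > 0:
            alliances = w_cc * f_ca / (cross * f_cc)
            mergers = w_cc * f_rd / (cross * f_cc)
        else:
            alliances = len(members) * f_ca / 2.0
            mergers = len(members) * f_rd / 2.0
        return {"w_cc": w_cc, "alliances": alliances, "mergers": mergers,
                "n_teams": len(members)}

    def true_lar_params(self) -> dict:
        """True lagged-association-rate parameters of the simulated process.

        For packing-off configurations the all-dyad rate is
        ``g(tau) = a2 + a3 exp(-a1 tau)`` with ``a1`` the alliance decay
        rate, and ``a2``/``a3`` the planted CC/CA shares corrected for the
        baseline probability ``q`` that any cross-team dyad happens to be
        re-associated on a given day (dissolved acquaintances can meet
        again at random): ``a2 = f_cc + (1 - f_cc) q``,
        ``a3 = f_ca (1 - q)``.
        """
        ss = self.steady_state()
        t = ss["n_teams"]
        n_cross = t * (t - 1) / 2.0
        q = (ss["alliances"] + ss["mergers"]) / n_cross if n_cross else 0.0
        f_cc, f_ca = self.config.cc_fraction, self.config.ca_fraction
        f_rd = 1.0 - f_cc - f_ca
        return {
            "a1": self.config.ca_decay_per_day,
            "a2": f_cc + (f_ca + f_rd) * q,
            "a3": f_ca * (1.0 - q),
            "baseline_q": q,
        }

    def unit_partition(self) -> dict:
        return {i: int(u) for i, u in zip(self.ids, self.unit)}

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "unit": self.unit.tolist(),
            "sex": self.sex.tolist(),
            "age_class": self.age_class.tolist(),
            "residency_class": self.residency_class.tolist(),
            "team_of": self.team_of.tolist(),
            "config": asdict(self.config),
        }


def generate_society(config: SocietyConfig) -> Society:
    """Build the ground-truth society (deterministic under config.seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"IND{k + 1:02d}" for k in range(n)]

    if config.unit_assignment is not None:
        unit = np.asarray(config.unit_assignment, dtype=int)
        if len(unit) != n:
            raise ValueError("unit_assignment length mismatch")
    else:
        unit = np.sort(np.arange(n) % config.n_units)

    sex = _allocate(config.sex_counts, n, rng)
    age = _allocate(config.age_counts, n, rng)
    res = _allocate(config.residency_counts, n, rng)
    # calves ride with an adult female: give them her residency
    females = np.flatnonzero((sex == "F") & (age == "A"))
    for i in np.flatnonzero(age == "C"):
        if len(females):
            mother = int(rng.choice(females))
            res[i] = res[mother]
            unit[i] = unit[mother]

    # CC teams: pair individuals within units (calves join the mother's team)
    team_of = np.full(n, -1, dtype=int)
    next_team = 0
    if config.cc_fraction > 0:
        for u in np.unique(unit):
            members = np.flatnonzero((unit == u) & (age != "C"))
            rng.shuffle(members)
            for k in range(0, len(members) - 1, 2):
                team_of[members[k]] = team_of[members[k + 1]] = next_team
                next_team += 1
            if len(members) % 2:
                team_of[members[-1]] = next_team
                next_team += 1
    else:
        for i in np.flatnonzero(age != "C"):
            team_of[i] = next_team
            next_team += 1
    for i in np.flatnonzero(age == "C"):            # calf -> mother's team
        u_females = np.flatnonzero((unit == unit[i]) & (sex == "F") & (age == "A"))
        anchor = int(rng.choice(u_females)) if len(u_females) else int(
            rng.choice(np.flatnonzero((unit == unit[i]) & (age != "C")))
        )
        team_of[i] = team_of[anchor]

    prop = np.where(
        unit[:, None] == unit[None, :],
        config.within_unit_alpha,
        config.between_unit_alpha,
    ).astype(float)
    np.fill_diagonal(prop, 0.0)
    return Society(
        ids=ids, unit=unit, sex=sex, age_class=age, residency_class=res,
        team_of=team_of, propensity=prop, config=config,
    )


# ---------------------------------------------------------------------------
# daily dynamics
# ---------------------------------------------------------------------------

def _team_propensity(society: Society, t1: list, t2: list) -> float:
    sub = society.propensity[np.ix_(t1, t2)]
    return float(sub.mean()) if sub.size else 0.0


def _weighted_pair(rng, teams: list, weights: dict) -> tuple:
    """Sample an unordered team pair with probability proportional to weight."""
    pairs = [(a, b) for ai, a in enumerate(teams) for b in teams[ai + 1:]]
    w = np.array([max(weights.get((a, b), 0.0), 1e-12) for a, b in pairs])
    return pairs[rng.choice(len(pairs), p=w / w.sum())]


def _dates(config: SocietyConfig) -> list:
    days_per_season = max(config.n_days // config.n_seasons, 1)
    out = []
    d = 0
    for s in range(config.n_seasons):
        start = np.datetime64(
            f"{config.first_year + s}{config.season_start}", "D"
        )
        for k in range(days_per_season):
            out.append(start + np.timedelta64(k, "D"))
            d += 1
            if d >= config.n_days:
                return out
    while d < config.n_days:                       # spill into the last season
        out.append(out[-1] + np.timedelta64(1, "D"))
        d += 1
    return out


def simulate_sightings(society: Society, config: SocietyConfig | None = None) -> SightingTable:
    """Simulate daily surveys of the society and emit a valid sighting table.

    Team alliances persist with daily survival ``exp(-ca_decay_per_day)``;
    their steady-state number and the number of one-day mergers are derived
    from ``cc_fraction``/``ca_fraction`` so the planted dyad-weight shares
    match the configured CC/CA/RD mixture.  Observation draws survey days
    and a limited number of focal groups per day, so the sighting record is
    a partial sample of the society as in real photo-identification work.
    """
    if config is None:
        config = society.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_individuals

    team_members = society.team_members()
    teams = sorted(team_members)

    pair_w = {}
    for ai, a in enumerate(teams):
        for b in teams[ai + 1:]:
            pair_w[(a, b)] = _team_propensity(
                society, team_members[a], team_members[b]
            )
    ss = society.steady_state()
    target_alliances = ss["alliances"]
    target_mergers = ss["mergers"]
    dissolve_p = 1.0 - np.exp(-config.ca_decay_per_day)

    sight_p = np.array(
        [config.daily_sighting_probability[c] for c in society.residency_class]
    )

    alliances: set[tuple] = set()
    rows = []
    for day_idx, date in enumerate(_dates(config)):
        # --- social state update -------------------------------------
        alliances = {al for al in alliances if rng.random() > dissolve_p}
        engaged = {t for al in alliances for t in al}
        free = [t for t in teams if t not in engaged]
        want = int(np.floor(target_alliances))
        if rng.random() < target_alliances - want:
            want += 1
        while len(alliances) < want and len(free) >= 2:
            a, b = _weighted_pair(rng, free, pair_w)
            alliances.add((a, b))
            free = [t for t in free if t not in (a, b)]

        mergers = set()
        want_m = int(np.floor(target_mergers))
        if rng.random() < target_mergers - want_m:
            want_m += 1
        free_m = list(free)
        while len(mergers) < want_m and len(free_m) >= 2:
            a, b = _weighted_pair(rng, free_m, pair_w)
            mergers.add((a, b))
            free_m = [t for t in free_m if t not in (a, b)]

        # --- presence and atom assembly ------------------------------
        present = rng.random(n) < sight_p
        # calves only ever present with their team (mother)
        atom_of = {}
        atoms: dict[int, list[int]] = {}
        for t in teams:
            atom_of[t] = t
        for a, b in alliances | mergers:
            atom_of[b] = atom_of[a]
        for t in teams:
            members = [i for i in team_members[t] if present[i]]
            if members:
                atoms.setdefault(atom_of[t], []).append(t)
        atom_groups = [
            sorted(i for t in ts for i in team_members[t] if present[i])
            for ts in atoms.values()
        ]
        atom_groups = [g for g in atom_groups if g]

        # --- optional packing into larger groups ---------------------
        if config.group_packing and len(atom_groups) > 1:
            order = rng.permutation(len(atom_groups))
            remaining = [atom_groups[k] for k in order]
            groups = []
            current = remaining.pop(0)
            while remaining:
                if len(current) >= rng.poisson(config.mean_group_size) + 1:
                    groups.append(current)
                    current = remaining.pop(0)
                    continue
                w = np.array(
                    [
                        max(
                            _team_propensity(society, current, cand), 1e-12
                        )
                        for cand in remaining
                    ]
                )
                pick = int(rng.choice(len(remaining), p=w / w.sum()))
                current = sorted(current + remaining.pop(pick))
            groups.append(current)
        else:
            groups = atom_groups

        # --- observation ---------------------------------------------
        if rng.random() > config.survey_probability:
            continue
        groups = [g for g in groups if g]
        if not groups:
            continue
        k_obs = (
            len(groups)
            if config.groups_observed_per_day is None
            else min(config.groups_observed_per_day, len(groups))
        )
        chosen = rng.choice(len(groups), size=k_obs, replace=False)
        for gnum, gi in enumerate(sorted(chosen)):
            g = groups[gi]
            units_in = society.unit[g]
            major_unit = int(np.bincount(units_in).argmax())
            trammel = bool(
                rng.random() < config.trammel_probability.get(major_unit, 0.3)
            )
            lo, hi = config.identified_fraction_range
            idf = rng.uniform(lo, hi)
            size_obs = max(len(g), int(round(len(g) / idf)))
            for i in g:
                rows.append(
                    {
                        "date": pd.Timestamp(date),
                        "time": gnum,
                        "group_id": f"D{day_idx:04d}G{gnum}",
                        "individual_id": society.ids[i],
                        "sex": society.sex[i],
                        "age_class": society.age_class[i],
                        "group_size_observed": size_obs,
                        "n_identified": len(g),
                        "trammel_net": trammel,
                    }
                )
    if not rows:
        raise ValueError(
            "simulation produced no sightings; raise survey_probability or n_days"
        )
    return SightingTable(pd.DataFrame(rows))
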