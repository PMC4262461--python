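"""Group-permutation null models and matrix tests for non-random association.

The null model permutes group memberships *within daily sampling periods*
via checkerboard flips: pick two groups from the same day and two animals in
the checkerboard pattern (first animal in group 1 only, second in group 2
only) and swap them.  Every flip preserves all group sizes (row sums) and all
per-period individual sighting counts (column sums), so the null conditions
on gregariousness and daily presence, accounting for birth, death and
migration across the study.  If animals have preferred or avoided
companions, the standard deviation (SD) of the observed half-weight indices
exceeds the permuted SD; the coefficient of variation (CV) is the sharper
statistic for *long-term* preferences because short-term preferences depress
the mean.

Sampling follows the sequential-chain convention: one long chain of flips,
sampled every ``flips_per_permutation`` successful flips, after a burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats as sps

from .association import hwi_from_matrix
from .sightings import GroupByIndividual

__all__ = [
    "PermutationResult",
    "UnswappableDataError",
    "GbiChain",
    "permutation_test",
    "stabilized_pvalue",
    "mantel_test",
    "dyad_class_chisquare",
    "checkerboard_flip",
]

DEFAULT_BURN_IN = 10_000


class UnswappableDataError(RuntimeError):
    """No feasible checkerboard flip exists anywhere in the matrix."""


# ---------------------------------------------------------------------------
# jitted flip chain (xorshift64* PRNG for bit-for-bit reproducibility)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _xs_next(s):
    s ^= s << np.uint64(13)
    s ^= s >> np.uint64(7)
    s ^= s << np.uint64(17)
    return s


@njit(cache=True, inline="always")
def _randbelow(s, n):
    s = _xs_next(s)
    return s, np.int64(s % np.uint64(n))


@njit(cache=True)
def _run_flips(mat, starts, ends, n_success, max_consec_fail, state):
    """Perform ``n_success`` checkerboard flips in place.

    ``starts``/``ends`` give the row ranges of periods with >= 2 groups.
    Returns (attempts, new_state); attempts = -1 signals unswappable data.
    """
    n_cols = mat.shape[1]
    attempts = np.int64(0)
    n_per = len(starts)
    done = 0
    fails = 0
    while done < n_success:
        attempts += 1
        state, p = _randbelow(state, n_per)
        a = starts[p]
        b = ends[p]
        ngr = b - a
        state, g1 = _randbelow(state, ngr)
        state, g2 = _randbelow(state, ngr - 1)
        if g2 >= g1:
            g2 += 1
        r1 = a + g1
        r2 = a + g2
        # choose i uniformly among cols with mat[r1]=1, mat[r2]=0 via
        # reservoir counting; likewise j for the reverse pattern
        ni = 0
        nj = 0
        ii = -1
        jj = -1
        for c in range(n_cols):
            v1 = mat[r1, c]
            v2 = mat[r2, c]
            if v1 == 1 and v2 == 0:
                ni += 1
                state, r = _randbelow(state, ni)
                if r == 0:
                    ii = c
            elif v1 == 0 and v2 == 1:
                nj += 1
                state, r = _randbelow(state, nj)
                if r == 0:
                    jj = c
        if ni > 0 and nj > 0:
            mat[r1, ii] = 0
            mat[r2, ii] = 1
            mat[r2, jj] = 0
            mat[r1, jj] = 1
            done += 1
            fails = 0
        else:
            fails += 1
            if fails > max_consec_fail:
                return np.int64(-1), state
    return attempts, state


def _seed_to_state(seed: int) -> np.uint64:
    # splitmix64 step so that small consecutive seeds give unrelated streams
    with np.errstate(over="ignore"):
        z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z | np.uint64(1)


class GbiChain:
    """Sequential chain of marginal-preserving flips over a GBI matrix.

    The matrix is copied; rows are kept in period order.  ``step(k)``
    advances the chain by ``k`` successful flips and returns the current
    matrix (a view -- copy if you need to keep it).
    """

    def __init__(self, gbi: GroupByIndividual, seed: int,
                 max_consec_fail: int = 100_000):
        self.matrix = np.ascontiguousarray(gbi.matrix, dtype=np.int8).copy()
        pid = gbi.period_indices()
        if not (np.diff(pid) >= 0).all():
            order = np.argsort(pid, kind="stable")
            self.matrix = self.matrix[order]
            pid = pid[order]
        # contiguous row ranges per period, keeping only periods with >=2 groups
        boundaries = np.flatnonzero(np.diff(pid)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(pid)]))
        keep = (ends - starts) >= 2
        if not keep.any():
            raise UnswappableDataError(
                "no sampling period contains two or more groups"
            )
        self._starts = starts[keep].astype(np.int64)
        self._ends = ends[keep].astype(np.int64)
        self._state = _seed_to_state(int(seed))
        self._max_fail = max_consec_fail
        self.total_attempts = 0
        self.total_flips = 0

    def step(self, n_flips: int) -> np.ndarray:
        attempts, state = _run_flips(
            self.matrix, self._starts, self._ends,
            np.int64(n_flips), np.int64(self._max_fail), self._state,
        )
        self._state = np.uint64(state)
        if attempts < 0:
            raise UnswappableDataError(
                "no feasible checkerboard flip found: the group-by-individual "
                "matrix admits no marginal-preserving swap"
            )
        self.total_attempts += int(attempts)
        self.total_flips += int(n_flips)
        return self.matrix


def checkerboard_flip(gbi: GroupByIndividual, seed: int) -> GroupByIndividual:
    """Apply one random within-period checkerboard flip; returns a new GBI."""
    chain = GbiChain(gbi, seed)
    mat = chain.step(1).copy()
    return GroupByIndividual(
        mat, gbi.individuals, gbi.periods, gbi.row_covariates,
        gbi.column_attributes,
    )


# ---------------------------------------------------------------------------
# permutation test on HWI summary statistics
# ---------------------------------------------------------------------------

def _offdiag_stats(matrix: np.ndarray) -> tuple[float, float, float]:
    """(SD, CV, mean) of unordered off-diagonal HWIs (masked dyads dropped)."""
    hwi, _, _ = hwi_from_matrix(matrix)
    iu = np.triu_indices(hwi.shape[0], k=1)
    v = hwi[iu]
    v = v[~np.isnan(v)]
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    cv = sd / mean if mean > 0 else np.nan
    return sd, cv, mean


@dataclass
class PermutationResult:
    """Null distribution of one HWI summary statistic under group permutation.

    ``p_greater`` uses the add-one convention (r+1)/(n+1) for the fraction of
    permuted values >= observed; ``p_less`` is the complement tail (both are
    reported because published work quotes either direction).
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_permutations: int
    flips_per_permutation: int
    seed: int
    p_greater: float = field(init=False)
    p_less: float = field(init=False)

    def __post_init__(self):
        null = np.asarray(self.null_values, dtype=float)
        n = len(null)
        self.p_greater = float((np.sum(null >= self.observed) + 1) / (n + 1))
        self.p_less = float((np.sum(null <= self.observed) + 1) / (n + 1))

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    def significant(self, level: float = 0.05) -> bool:
        """Two-sided call at ``level``: either tail below level/2."""
        return min(self.p_greater, self.p_less) <= level / 2.0


def permutation_test(
    gbi: GroupByIndividual,
    n_permutations: int = 1000,
    flips_per_permutation: int = 1000,
    seed: int = 0,
    burn_in: int = DEFAULT_BURN_IN,
) -> dict[str, PermutationResult]:
    """Within-period group-permutation test of the SD, CV and mean of HWIs.

    One sequential chain: ``burn_in`` successful flips, then one sample every
    ``flips_per_permutation`` successful flips, recomputing the HWI matrix at
    each sample.  A significantly high observed SD indicates preferred /
    avoided companions; a significantly high CV indicates *long-term*
    preferred companions.
    """
    obs_sd, obs_cv, obs_mean = _offdiag_stats(gbi.matrix)
    chain = GbiChain(gbi, seed)
    if burn_in:
        chain.step(burn_in)
    null = np.empty((n_permutations, 3))
    for k in range(n_permutations):
        mat = chain.step(flips_per_permutation)
        null[k] = _offdiag_stats(mat)
    out = {}
    for idx, (name, obs) in enumerate(
        (("SD", obs_sd), ("CV", obs_cv), ("mean", obs_mean))
    ):
        out[name] = PermutationResult(
            statistic_name=name,
            observed=obs,
            null_values=null[:, idx].copy(),
            n_permutations=n_permutations,
            flips_per_permutation=flips_per_permutation,
            seed=seed,
        )
    return out


def stabilized_pvalue(
    gbi: GroupByIndividual,
    statistic: str = "CV",
    seed: int = 0,
    start_n: int = 100,
    tolerance: float = 0.001,
    flips_per_permutation: int = 1000,
    cap: int = 1_000_000,
) -> tuple[float, int, bool]:
    """Double the permutation count until the p-value stabilizes.

    Returns ``(p_greater, n_used, stable)``; ``stable`` is False when the
    cap was reached before successive estimates differed by < ``tolerance``.
    Deterministic for a fixed seed.
    """
    if start_n < 100:
        raise ValueError("start_n must be >= 100")
    n = start_n
    prev_p = None
    while True:
        res = permutation_test(
            gbi, n_permutations=n,
            flips_per_permutation=flips_per_permutation, seed=seed,
        )[statistic]
        p = res.p_greater
        if prev_p is not None and abs(p - prev_p) < tolerance:
            return p, n, True
        if n >= cap:
            return p, n, False
        prev_p = p
        n = min(2 * n, cap)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel matrix correlation with simultaneous row/column permutation.

    ``r`` is the Pearson correlation of the unordered off-diagonal elements;
    the null permutes the labels of ``m2``.  Two-sided p with the add-one
    convention.  Used e.g. to test whether association level depends on sex
    (``m2`` a sex-similarity matrix).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square with identical shape")
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if np.nanstd(v1) < 1e-12 or np.nanstd(m2[iu]) < 1e-12:
        raise ValueError("Mantel correlation undefined for a constant matrix")

    def corr(perm: np.ndarray) -> float:
        v2 = m2[np.ix_(perm, perm)][iu]
        ok = ~(np.isnan(v1) | np.isnan(v2))
        return float(np.corrcoef(v1[ok], v2[ok])[0, 1])

    rng = np.random.default_rng(seed)
    r_obs = corr(np.arange(n))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if abs(corr(perm)) >= abs(r_obs):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return r_obs, float(p)


def dyad_class_chisquare(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a (dyad HWI class x sex pairing) table.

    ``counts`` is a 2-D array of non-negative integers.  Raises if any
    expected cell is zero (merge bins first).
    """
    table = np.asarray(counts, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError(
            "zero expected cell count: merge sparse HWI classes before testing"
        )
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)
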