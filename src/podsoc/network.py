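"""Weighted social-network metrics and the social-differentiation estimate.

Metrics operate on the half-weight index matrix: *strength* (weighted
degree: sum of an individual's association indices, a measure of
gregariousness), *clustering coefficient* (weighted triangle closure: the
extent to which an individual's associates are themselves associated) and
*affinity* (association-weighted mean strength of associates: do strongly
connected animals link to other strongly connected animals?).

*Social differentiation* S is the coefficient of variation of the **true**
association indices, i.e. corrected for sampling error: observed joint
counts are modelled as binomial draws whose success probabilities follow a
beta distribution across dyads, and S is the CV of that beta.  S ~ 0
indicates a homogeneous society; S > 0.5 a well-differentiated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .association import AssociationMatrix, hwi_from_matrix
from .permutation import GbiChain, PermutationResult
from .sightings import GroupByIndividual

__all__ = [
    "strength",
    "clustering_coefficient",
    "affinity",
    "metric_significance",
    "bootstrap_se",
    "SocialDifferentiationModel",
    "SocialDifferentiationResult",
    "social_differentiation",
    "metric_table",
]


def _weights(am_or_hwi) -> np.ndarray:
    """Dense weight matrix with zero diagonal and NaNs treated as no edge."""
    hwi = am_or_hwi.hwi if isinstance(am_or_hwi, AssociationMatrix) else am_or_hwi
    w = np.array(hwi, dtype=float)
    w[np.isnan(w)] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def strength(am) -> np.ndarray:
    """Per-individual sum of association indices (row sums, diagonal excluded)."""
    return _weights(am).sum(axis=1)


def clustering_coefficient(am) -> np.ndarray:
    """Weighted clustering coefficient in [0, 1] per individual.

    ``C_i = sum_{j,k} w_ij w_jk w_ki / (max(w) * sum_{j != k} w_ij w_ik)``,
    the weighted proportion of an individual's neighbour pairs that are
    themselves connected, normalised by the matrix maximum so a binary
    clique scores 1.  NaN where the individual has fewer than two weighted
    neighbours (denominator zero).
    """
    w = _weights(am)
    wmax = w.max()
    if wmax == 0:
        return np.full(w.shape[0], np.nan)
    triangles = np.diag(w @ w @ w)                       # sum_jk w_ij w_jk w_ki
    s = w.sum(axis=1)
    open_triads = s**2 - (w**2).sum(axis=1)              # sum_{j != k} w_ij w_ik
    with np.errstate(invalid="ignore", divide="ignore"):
        c = triangles / (wmax * open_triads)
    c[open_triads <= 0] = np.nan
    return c


def affinity(am) -> np.ndarray:
    """Weighted mean strength of an individual's neighbours.

    ``a_i = sum_j w_ij s_j / s_i``; NaN for zero-strength individuals.
    """
    w = _weights(am)
    s = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (w @ s) / s
    a[s == 0] = np.nan
    return a


_METRICS = {
    "strength": strength,
    "clustering_coefficient": clustering_coefficient,
    "affinity": affinity,
}


def metric_table(am: AssociationMatrix) -> pd.DataFrame:
    """All three per-individual metrics as one frame."""
    return pd.DataFrame(
        {name: fn(am) for name, fn in _METRICS.items()},
        index=list(am.individuals),
    )


def metric_significance(
    gbi: GroupByIndividual,
    metric: str = "clustering_coefficient",
    n_permutations: int = 1000,
    flips_per_permutation: int = 1000,
    seed: int = 0,
    burn_in: int = 10_000,
) -> PermutationResult:
    """Permutation significance of the population-mean network metric.

    The null distribution of the mean metric comes from the same
    within-period flip chain as the association permutation test.
    """
    fn = _METRICS[metric]

    def mean_metric(matrix: np.ndarray) -> float:
        hwi, _, _ = hwi_from_matrix(matrix)
        return float(np.nanmean(fn(hwi)))

    observed = mean_metric(gbi.matrix)
    chain = GbiChain(gbi, seed)
    if burn_in:
        chain.step(burn_in)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = mean_metric(chain.step(flips_per_permutation))
    return PermutationResult(
        statistic_name=f"mean_{metric}",
        observed=observed,
        null_values=null,
        n_permutations=n_permutations,
        flips_per_permutation=flips_per_permutation,
        seed=seed,
    )


def bootstrap_se(
    gbi: GroupByIndividual,
    metric: str = "strength",
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-individual bootstrap standard error of a network metric.

    Group sightings (GBI rows) are the resampling unit: rows are resampled
    with replacement, the HWI matrix and metric recomputed, and the SE is
    the standard deviation across replicates.
    """
    fn = _METRICS[metric]
    mat = gbi.matrix
    n_groups = mat.shape[0]
    if n_groups < 2:
        warnings.warn("bootstrap over a single group is degenerate; SEs are 0")
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        rows = rng.integers(0, n_groups, size=n_groups)
        hwi, _, _ = hwi_from_matrix(mat[rows])
        reps[b] = fn(hwi)
    return np.nanstd(reps, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# social differentiation
# ---------------------------------------------------------------------------

@dataclass
class SocialDifferentiationResult:
    """Maximum-likelihood social differentiation estimate.

    ``s`` is the CV of the fitted beta distribution of true association
    indices, ``se`` its delete-one-individual jackknife standard error, and
    ``s_mom`` an independent method-of-moments estimate for comparison.
    ``well_differentiated`` applies the conventional S > 0.5 threshold.
    """

    s: float
    se: float
    alpha: float
    beta: float
    loglik: float
    s_mom: float
    converged: bool
    n_dyads: int

    @property
    def well_differentiated(self) -> bool:
        return self.s > 0.5

    def summary(self) -> str:
        lines = [
            "Social differentiation (CV of true association indices)",
            "=" * 56,
            f"S (maximum likelihood)   {self.s:8.3f}  (SE {self.se:.3f}, jackknife)",
            f"S (method of moments)    {self.s_mom:8.3f}",
            f"beta parameters          a={self.alpha:.3f}, b={self.beta:.3f}",
            f"log-likelihood           {self.loglik:10.3f}   dyads: {self.n_dyads}",
            f"well differentiated (>0.5): {'yes' if self.well_differentiated else 'no'}",
        ]
        if not self.converged:
            lines.append("warning: optimizer did not converge; method-of-moments "
                         "estimate reported")
        return "\n".join(lines)


class SocialDifferentiationModel:
    """Beta-binomial model of dyadic joint-sighting counts.

    Each dyad's joint-sighting count ``x_ij`` is binomial with ``n_ij``
    effective trials (the half-weight denominator ``(d_i + d_j) / 2``) and a
    true index drawn from Beta(a, b); the CV of that beta is the social
    differentiation S.  Fit by bounded 2-parameter maximum likelihood
    (relative tolerance 1e-8) with a method-of-moments fallback.
    """

    def __init__(self, am: AssociationMatrix):
        self.am = am
        iu, ju = am.dyad_index()
        d = am.d
        n_eff = np.ceil((d[iu] + d[ju]) / 2.0).astype(int)
        keep = n_eff > 0
        self.x = am.x[iu, ju].astype(int)[keep]
        self.n = n_eff[keep]
        self._iu, self._ju = iu[keep], ju[keep]

    @staticmethod
    def _cv(a: float, b: float) -> float:
        return float(np.sqrt(b / (a * (a + b + 1.0))))

    def _negloglik(self, log_ab: np.ndarray, x=None, n=None) -> float:
        a, b = np.exp(log_ab)
        x = self.x if x is None else x
        n = self.n if n is None else n
        return -float(sps.betabinom.logpmf(x, n, a, b).sum())

    def _fit_ab(self, x, n) -> tuple[float, float, float, bool]:
        p_hat = x / n
        m = float(np.clip(p_hat.mean(), 1e-6, 1 - 1e-6))
        v = float(p_hat.var())
        # moment-matched start
        if 0 < v < m * (1 - m):
            nu = m * (1 - m) / v - 1
        else:
            nu = 10.0
        best = None
        for start_nu in (nu, 1.0, 50.0):
            x0 = np.log(np.maximum([m * start_nu, (1 - m) * start_nu], 1e-6))
            res = optimize.minimize(
                self._negloglik, x0, args=(x, n), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        a, b = np.exp(best.x)
        return float(a), float(b), -float(best.fun), bool(best.success)

    def mom_estimate(self) -> float:
        """Method-of-moments S: observed index variance minus its expected
        binomial sampling component, over the squared mean."""
        p = self.x / self.n
        mean = p.mean()
        samp_var = (p * (1 - p) / self.n).mean()
        true_var = max(p.var() - samp_var, 0.0)
        return float(np.sqrt(true_var) / mean) if mean > 0 else 0.0

    def fit(self, jackknife: bool = True) -> SocialDifferentiationResult:
        p = self.x / self.n
        if np.allclose(p, p[0]):
            return SocialDifferentiationResult(
                s=0.0, se=0.0, alpha=np.nan, beta=np.nan, loglik=np.nan,
                s_mom=0.0, converged=True, n_dyads=len(self.x),
            )
        a, b, ll, ok = self._fit_ab(self.x, self.n)
        s_mom = self.mom_estimate()
        if not ok:
            warnings.warn(
                "social-differentiation likelihood failed to converge; "
                "falling back to method of moments"
            )
            s = s_mom
        else:
            s = self._cv(a, b)

        se = np.nan
        if jackknife:
            n_ind = self.am.n
            thetas = []
            for i in range(n_ind):
                keep = (self._iu != i) & (self._ju != i)
                if keep.sum() < 3:
                    continue
                aa, bb, _, okk = self._fit_ab(self.x[keep], self.n[keep])
                thetas.append(self._cv(aa, bb) if okk else np.nan)
            thetas = np.array([t for t in thetas if np.isfinite(t)])
            if len(thetas) >= 3:
                bcount = len(thetas)
                se = float(
                    np.sqrt((bcount - 1) / bcount * ((thetas - thetas.mean()) ** 2).sum())
                )
        return SocialDifferentiationResult(
            s=float(s), se=se, alpha=a, beta=b, loglik=ll, s_mom=s_mom,
            converged=ok, n_dyads=len(self.x),
        )


def social_differentiation(
    am: AssociationMatrix, jackknife: bool = True
) -> SocialDifferentiationResult:
    """Convenience wrapper: fit the beta-binomial model and return S with SE."""
    return SocialDifferentiationModel(am).fit(jackknife=jackknife)
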