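"""Lagged association rates and exponential-decay models of social stability.

The lagged association rate g(tau) is the probability that two animals
associated at some time are still associated tau days later, estimated by a
ratio-of-sums over all ordered pairs of sampling periods: the numerator
accumulates pairs associated at both periods, the denominator pairs
associated at the earlier period whose first member was identified at the
later one.  g(tau) is compared with the *null association rate* -- the rate
expected were animals associating at random given their gregariousness --
and fitted with an eight-member family of exponential-decay models built
from three components: constant companions (CC, permanent), casual
acquaintances (CA, decaying over a characteristic number of days, the
reciprocal of the decay rate) and rapid disassociations (RD, gone by the
next sampling period).  Because the pair-period counts are heavily
overdispersed, models are ranked by QAIC with the overdispersion factor
estimated from the most general model; standard errors come from a
delete-one-block jackknife over contiguous date blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .sightings import GroupByIndividual

__all__ = [
    "LARCurve",
    "LARModelFit",
    "LARFitResults",
    "LaggedAssociationModel",
    "lagged_association_rate",
    "null_association_rate",
    "fit_lar_models",
    "jackknife_errors",
    "MODEL_FORMS",
]

_EPS = 1e-10


# ---------------------------------------------------------------------------
# model family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ModelForm:
    name: str
    components: tuple[str, ...]
    param_names: tuple[str, ...]    # a* = level-1 (rate a1, CC prop a2, CA prop a3)
    bounds: tuple[tuple[float, float], ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


def _g_cc(tau, p):
    return np.ones_like(tau, dtype=float)


def _g_ca(tau, p):
    return np.exp(-p[0] * tau)


def _g_cc_ca(tau, p):
    return p[1] + (1.0 - p[1]) * np.exp(-p[0] * tau)


def _g_rd_cc(tau, p):
    return np.full_like(tau, p[0], dtype=float)


def _g_rd_ca(tau, p):
    return p[1] * np.exp(-p[0] * tau)


def _g_rd_cc_ca(tau, p):
    return p[1] + p[2] * np.exp(-p[0] * tau)


def _g_2ca(tau, p):
    return p[1] * np.exp(-p[0] * tau) + (1.0 - p[1]) * np.exp(-p[2] * tau)


def _g_rd_2ca(tau, p):
    return p[1] * np.exp(-p[0] * tau) + p[3] * np.exp(-p[2] * tau)


_RATE = (1e-6, 20.0)
_PROP = (0.0, 1.0)

#: the eight standard forms: every combination of constant companions (CC),
#: casual acquaintances (CA, one or two decay scales) and rapid
#: disassociation (RD; present whenever g(0+) may fall below 1).
MODEL_FORMS: dict[str, tuple[_ModelForm, callable]] = {
    "CC": (_ModelForm("CC", ("CC",), (), ()), _g_cc),
    "CA": (_ModelForm("CA", ("CA",), ("a1",), (_RATE,)), _g_ca),
    "CC+CA": (
        _ModelForm("CC+CA", ("CC", "CA"), ("a1", "a2"), (_RATE, _PROP)),
        _g_cc_ca,
    ),
    "RD+CC": (_ModelForm("RD+CC", ("RD", "CC"), ("a2",), (_PROP,)), _g_rd_cc),
    "RD+CA": (
        _ModelForm("RD+CA", ("RD", "CA"), ("a1", "a3"), (_RATE, _PROP)),
        _g_rd_ca,
    ),
    "RD+CC+CA": (
        _ModelForm(
            "RD+CC+CA", ("RD", "CC", "CA"), ("a1", "a2", "a3"),
            (_RATE, _PROP, _PROP),
        ),
        _g_rd_cc_ca,
    ),
    "2CA": (
        _ModelForm("2CA", ("CA", "CA2"), ("a1", "a2", "b1"),
                   (_RATE, _PROP, _RATE)),
        _g_2ca,
    ),
    "RD+2CA": (
        _ModelForm("RD+2CA", ("RD", "CA", "CA2"), ("a1", "a2", "b1", "b2"),
                   (_RATE, _PROP, _RATE, _PROP)),
        _g_rd_2ca,
    ),
}

#: most general form; its deviance/df estimates the overdispersion c-hat
_GENERAL_MODEL = "RD+2CA"


# ---------------------------------------------------------------------------
# pairwise period accumulation
# ---------------------------------------------------------------------------

def _period_arrays(gbi: GroupByIndividual):
    """Per-period association and observation indicators.

    Returns (dates, A, O): A[(p, i*n+j)] flattened ordered-pair association
    indicator, O[p, i] observation indicator.
    """
    uniq = np.unique(gbi.periods)
    pid = np.searchsorted(uniq, gbi.periods)
    n = gbi.n_individuals
    n_per = len(uniq)
    a = np.zeros((n_per, n, n), dtype=np.float32)
    for row in range(gbi.matrix.shape[0]):
        members = np.flatnonzero(gbi.matrix[row])
        if members.size >= 2:
            a[pid[row]][np.ix_(members, members)] = 1.0
    for p in range(n_per):
        np.fill_diagonal(a[p], 0.0)
    o = np.zeros((n_per, n), dtype=bool)
    for row in range(gbi.matrix.shape[0]):
        o[pid[row]] |= gbi.matrix[row].astype(bool)
    days = (uniq - uniq.min()).astype("timedelta64[D]").astype(int)
    return days, a, o.astype(np.float32)


def _pair_period_counts(gbi: GroupByIndividual):
    """Numerator/denominator/lag for every ordered period pair (t < t').

    num[t, t'] = ordered pairs associated at both t and t';
    den[t, t'] = ordered pairs associated at t with the first member
    identified at t'.
    """
    days, a, o = _period_arrays(gbi)
    n_per = len(days)
    flat = a.reshape(n_per, -1)
    num = flat @ flat.T
    assoc_count = a.sum(axis=2)              # per-period associates of each i
    den = assoc_count @ o.T
    lag = days[None, :] - days[:, None]
    upper = lag > 0
    return num[upper], den[upper], lag[upper], np.nonzero(upper)


# ---------------------------------------------------------------------------
# curve estimation
# ---------------------------------------------------------------------------

def _default_bins(max_lag: int, n_bins: int = 12) -> np.ndarray:
    """Log-spaced lag bin edges over [1, max_lag]."""
    if max_lag <= 1:
        return np.array([1.0, 2.0])
    edges = np.unique(np.round(np.geomspace(1, max_lag + 1, n_bins + 1)))
    return edges.astype(float)


def _bin_counts(num, den, lag, edges, min_per_bin):
    """Aggregate pair-period counts into lag bins; merge sparse bins upward."""
    idx = np.digitize(lag, edges) - 1
    nb = len(edges) - 1
    bnum = np.zeros(nb)
    bden = np.zeros(nb)
    btau = np.zeros(nb)
    for b in range(nb):
        sel = idx == b
        bnum[b] = num[sel].sum()
        bden[b] = den[sel].sum()
        btau[b] = (lag[sel] * den[sel]).sum()
    # merge bins with thin denominators into the next bin up
    out_num, out_den, out_tau = [], [], []
    acc = np.zeros(3)
    for b in range(nb):
        acc += (bnum[b], bden[b], btau[b])
        if acc[1] >= min_per_bin:
            out_num.append(acc[0])
            out_den.append(acc[1])
            out_tau.append(acc[2])
            acc = np.zeros(3)
    if acc[1] > 0:
        if out_den:
            out_num[-1] += acc[0]
            out_den[-1] += acc[1]
            out_tau[-1] += acc[2]
        else:
            out_num.append(acc[0])
            out_den.append(acc[1])
            out_tau.append(acc[2])
    bnum = np.array(out_num)
    bden = np.array(out_den)
    tau = np.array(out_tau) / np.maximum(bden, 1.0)
    return bnum, bden, tau


@dataclass
class LARCurve:
    """Estimated lagged association rate with jackknife errors.

    ``tau`` is the denominator-weighted mean lag per bin (days), ``g`` the
    ratio-of-sums estimate, ``se`` the delete-one-date-block jackknife SE and
    ``null_rate`` the random-association expectation.
    """

    tau: np.ndarray
    g: np.ndarray
    se: np.ndarray
    num: np.ndarray
    den: np.ndarray
    null_rate: float
    block_days: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau_days": self.tau, "g": self.g, "se": self.se,
             "numerator": self.num, "denominator": self.den}
        )


def null_association_rate(gbi: GroupByIndividual) -> float:
    """Expected association rate under random mixing.

    With mean identified group size k and N identified individuals, a random
    associate of an animal is any one of the other N - 1 with equal
    probability, so the chance that a *specific* previous associate is drawn
    again is (k - 1) / (N - 1).
    """
    k = gbi.matrix.sum(axis=1).mean()
    n = gbi.n_individuals
    if n < 2:
        return np.nan
    return float((k - 1.0) / (n - 1.0))


# ---------------------------------------------------------------------------
# model fit results
# ---------------------------------------------------------------------------

@dataclass
class LARModelFit:
    """One fitted exponential-decay model of the lagged association rate."""

    name: str
    components: tuple[str, ...]
    param_names: tuple[str, ...]
    params: np.ndarray
    logql: float
    deviance: float
    k: int                          # parameters + 1 for c-hat
    qaic: float = np.nan
    converged: bool = True
    jackknife_se: np.ndarray | None = None

    def predict(self, tau) -> np.ndarray:
        fn = MODEL_FORMS[self.name][1]
        return np.clip(fn(np.asarray(tau, dtype=float), self.params), 0.0, 1.0)

    @property
    def param_dict(self) -> dict:
        return dict(zip(self.param_names, self.params))

    def ca_duration_days(self) -> dict:
        """Characteristic acquaintance durations: reciprocal of each decay rate."""
        out = {}
        for nm, val in self.param_dict.items():
            if nm in ("a1", "b1") and val > 0:
                out[nm] = 1.0 / val
        return out

    def _structure(self) -> tuple[float, list[tuple[float, float]]]:
        """(constant level, [(decay rate, proportion), ...]) of the fitted g."""
        p = self.param_dict
        const = {"CC": 1.0, "RD+CC": p.get("a2", 0.0),
                 "CC+CA": p.get("a2", 0.0), "RD+CC+CA": p.get("a2", 0.0)}.get(
                     self.name, 0.0)
        decays = {
            "CC": lambda: [],
            "CA": lambda: [(p["a1"], 1.0)],
            "CC+CA": lambda: [(p["a1"], 1.0 - p["a2"])],
            "RD+CC": lambda: [],
            "RD+CA": lambda: [(p["a1"], p["a3"])],
            "RD+CC+CA": lambda: [(p["a1"], p["a3"])],
            "2CA": lambda: [(p["a1"], p["a2"]), (p["b1"], 1.0 - p["a2"])],
            "RD+2CA": lambda: [(p["a1"], p["a2"]), (p["b1"], p["b2"])],
        }[self.name]()
        return const, decays

    def effective_components(self, study_span_days: float, tol: float = 0.01
                             ) -> frozenset:
        """Structural components actually expressed over the study horizon.

        A fitted exponential whose characteristic duration (1/rate) exceeds
        the study span is indistinguishable from constant companionship and
        is classified as CC; components with negligible proportion (< tol)
        are dropped; a g(0+) below 1 - tol implies rapid disassociation.
        """
        const, decays = self._structure()
        comps = set()
        g0 = const
        for rate, prop in decays:
            g0 += prop
            if prop <= tol:
                continue
            if rate <= 1.0 / study_span_days:
                const += prop
            else:
                comps.add("CA")
        if const > tol:
            comps.add("CC")
        if g0 < 1.0 - tol:
            comps.add("RD")
        return frozenset(comps)


@dataclass
class LARFitResults:
    """Ranked model family with QAIC, in statsmodels Results style."""

    curve: LARCurve
    models: list[LARModelFit]
    c_hat: float

    @property
    def best(self) -> LARModelFit:
        return self.models[0]

    def table(self) -> pd.DataFrame:
        rows = []
        qmin = self.models[0].qaic
        for m in self.models:
            row = {
                "model": m.name,
                "components": "+".join(m.components),
                "K": m.k,
                "logQL": m.logql,
                "QAIC": m.qaic,
                "dQAIC": m.qaic - qmin,
                "converged": m.converged,
            }
            for nm, v in m.param_dict.items():
                row[nm] = v
            if m.jackknife_se is not None:
                for nm, s in zip(m.param_names, m.jackknife_se):
                    row[f"se_{nm}"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        qmin = self.models[0].qaic
        lines = [
            "Lagged association rate: exponential-decay model selection",
            "=" * 62,
            f"overdispersion c-hat = {self.c_hat:.3f} "
            f"(from {_GENERAL_MODEL}); null rate = {self.curve.null_rate:.4f}",
            "",
            f"{'model':<10} {'K':>2} {'QAIC':>14} {'dQAIC':>9}  parameters",
        ]
        for m in self.models:
            pstr = ", ".join(
                f"{nm}={v:.3f}" + (
                    f" (SE {s:.3f})" if m.jackknife_se is not None else ""
                )
                for (nm, v), s in zip(
                    m.param_dict.items(),
                    m.jackknife_se if m.jackknife_se is not None
                    else [np.nan] * len(m.params),
                )
            )
            flag = "" if m.converged else "  [not converged]"
            lines.append(
                f"{m.name:<10} {m.k:>2} {m.qaic:>14.4f} {m.qaic - qmin:>9.2f}  "
                f"{pstr}{flag}"
            )
        best = self.best
        dur = best.ca_duration_days()
        if dur:
            durs = ", ".join(f"1/{k} = {v:.1f} d" for k, v in dur.items())
            lines.append("")
            lines.append(f"best model {best.name}: acquaintance duration {durs}")
        lines.append(
            "dQAIC > 2 indicates essentially no support for that model."
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _neg_logql(params, fn, tau, num, den):
    g = np.clip(fn(tau, params), _EPS, 1.0 - _EPS)
    return -float(np.sum(num * np.log(g) + (den - num) * np.log1p(-g)))


def _saturated_logql(num, den):
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.clip(num / den, _EPS, 1.0 - _EPS)
    return float(np.sum(num * np.log(p) + (den - num) * np.log1p(-p)))


def _fit_one(name, tau, num, den, rng, n_starts=5, x0=None):
    form, fn = MODEL_FORMS[name]
    if form.k == 0:
        ll = -_neg_logql(np.empty(0), fn, tau, num, den)
        return np.empty(0), ll, True
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    while len(starts) < n_starts:
        s = []
        for nm, (lo, hi) in zip(form.param_names, form.bounds):
            if (lo, hi) == _RATE:
                s.append(np.exp(rng.uniform(np.log(0.005), np.log(2.0))))
            else:
                s.append(rng.uniform(0.05, 0.95))
        starts.append(np.array(s))
    best = None
    for s in starts:
        res = optimize.minimize(
            _neg_logql, s, args=(fn, tau, num, den), method="L-BFGS-B",
            bounds=form.bounds, options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -float(best.fun), bool(best.success)


# ---------------------------------------------------------------------------
# high-level model object
# ---------------------------------------------------------------------------

class LaggedAssociationModel:
    """Lagged association rate estimator and model family, built from a GBI.

    Parameters
    ----------
    gbi : GroupByIndividual
        Dated group sightings; sampling periods are the distinct dates.
    lag_bins : array-like, optional
        Lag bin edges in days; default log-spaced over the observed range,
        with bins merged upward until each holds at least ``min_per_bin``
        denominator counts.
    block_days : int
        Width of the contiguous date blocks used for all jackknife errors.
    """

    def __init__(
        self,
        gbi: GroupByIndividual,
        lag_bins=None,
        min_per_bin: int = 20,
        block_days: int = 30,
    ):
        if len(np.unique(gbi.periods)) < 2:
            raise ValueError("lagged association rate needs >= 2 sampling periods")
        self.gbi = gbi
        self.block_days = block_days
        self.min_per_bin = min_per_bin
        num, den, lag, (ti, tj) = _pair_period_counts(gbi)
        self._num, self._den, self._lag = num, den, lag
        self._ti, self._tj = ti, tj
        uniq = np.unique(gbi.periods)
        self._period_block = (
            (uniq - uniq.min()).astype("timedelta64[D]").astype(int) // block_days
        )
        if lag_bins is None:
            lag_bins = _default_bins(int(lag.max()))
        self.bin_edges = np.asarray(lag_bins, dtype=float)
        self._bnum, self._bden, self._btau = _bin_counts(
            num, den, lag, self.bin_edges, min_per_bin
        )
        if (self._bden <= 0).all():
            raise ValueError("no lag bin has a nonzero denominator")

    # -- curve ------------------------------------------------------------
    def _binned_excluding(self, block: int):
        keep = (self._period_block[self._ti] != block) & (
            self._period_block[self._tj] != block
        )
        return _bin_counts(
            self._num[keep], self._den[keep], self._lag[keep],
            self.bin_edges, self.min_per_bin,
        )

    def curve(self) -> LARCurve:
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(self._bden > 0, self._bnum / self._bden, np.nan)
        blocks = np.unique(self._period_block)
        if len(blocks) >= 3:
            reps = np.full((len(blocks), len(g)), np.nan)
            for bi, b in enumerate(blocks):
                bn, bd, bt = self._binned_excluding(b)
                gb = np.where(bd > 0, bn / np.maximum(bd, 1), np.nan)
                # align by interpolation on tau (bin merges may differ)
                reps[bi] = np.interp(self._btau, bt, gb)
            bcount = len(blocks)
            se = np.sqrt(
                (bcount - 1) / bcount
                * np.nansum((reps - np.nanmean(reps, axis=0)) ** 2, axis=0)
            )
        else:
            se = np.full(len(g), np.nan)
        return LARCurve(
            tau=self._btau, g=g, se=se, num=self._bnum, den=self._bden,
            null_rate=null_association_rate(self.gbi),
            block_days=self.block_days,
        )

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        models=tuple(MODEL_FORMS),
        seed: int = 0,
        n_starts: int = 5,
        jackknife: bool = True,
    ) -> LARFitResults:
        """Fit the model family by binomial quasi-likelihood and rank by QAIC.

        Overdispersion c-hat is the most-general model's deviance over its
        residual degrees of freedom; QAIC = deviance / c-hat + 2K with K the
        parameter count plus one for c-hat.  Parameter SEs come from the
        delete-one-block jackknife.  A model that fails to converge is
        flagged but still ranked.
        """
        rng = np.random.default_rng(seed)
        tau, num, den = self._btau, self._bnum, self._bden
        ll_sat = _saturated_logql(num, den)

        fits: dict[str, LARModelFit] = {}
        for name in models:
            form, _ = MODEL_FORMS[name]
            params, ll, ok = _fit_one(name, tau, num, den, rng, n_starts)
            fits[name] = LARModelFit(
                name=name,
                components=form.components,
                param_names=form.param_names,
                params=params,
                logql=ll,
                deviance=2.0 * (ll_sat - ll),
                k=form.k + 1,
                converged=ok,
            )

        gen_name = _GENERAL_MODEL if _GENERAL_MODEL in fits else max(
            fits, key=lambda n: fits[n].k
        )
        gen = fits[gen_name]
        df = len(tau) - (gen.k - 1)
        if df <= 0:
            warnings.warn(
                "too few lag bins to estimate overdispersion; using c-hat = 1"
            )
            c_hat = 1.0
        else:
            c_hat = max(gen.deviance / df, 1.0)

        for m in fits.values():
            m.qaic = m.deviance / c_hat + 2.0 * m.k

        if jackknife:
            blocks = np.unique(self._period_block)
            if len(blocks) >= 3:
                for name, m in fits.items():
                    if m.k - 1 == 0:
                        m.jackknife_se = np.empty(0)
                        continue
                    reps = []
                    for b in blocks:
                        bn, bd, bt = self._binned_excluding(b)
                        if bd.sum() == 0:
                            continue
                        pb, _, _ = _fit_one(
                            name, bt, bn, bd, rng, n_starts=1, x0=m.params
                        )
                        reps.append(pb)
                    reps = np.array(reps)
                    bc = len(reps)
                    if bc >= 3:
                        m.jackknife_se = np.sqrt(
                            (bc - 1) / bc * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0)
                        )

        ranked = sorted(fits.values(), key=lambda m: m.qaic)
        return LARFitResults(curve=self.curve(), models=ranked, c_hat=c_hat)


# ---------------------------------------------------------------------------
# functional wrappers and the generic jackknife
# ---------------------------------------------------------------------------

def lagged_association_rate(gbi: GroupByIndividual, lag_bins=None, **kw) -> LARCurve:
    """Estimate the lagged association rate curve (see LaggedAssociationModel)."""
    return LaggedAssociationModel(gbi, lag_bins=lag_bins, **kw).curve()


def fit_lar_models(
    gbi: GroupByIndividual, models=tuple(MODEL_FORMS), seed: int = 0, **kw
) -> LARFitResults:
    """Fit and rank the exponential-decay model family on a GBI."""
    jack = kw.pop("jackknife", True)
    return LaggedAssociationModel(gbi, **kw).fit(
        models=models, seed=seed, jackknife=jack
    )


def jackknife_errors(
    gbi: GroupByIndividual, estimator, block_days: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-block jackknife SE of any estimator of a GBI.

    Blocks are contiguous ``block_days``-day spans of the study; the
    estimator is recomputed with each block's groups removed and
    ``SE = sqrt((B-1)/B * sum((theta_b - theta_bar)^2))``.  Requires >= 3
    non-empty blocks.  Returns (se, per_block_estimates).
    """
    days = (gbi.periods - gbi.periods.min()).astype("timedelta64[D]").astype(int)
    block = days // block_days
    blocks = np.unique(block)
    if len(blocks) < 3:
        raise ValueError(
            f"jackknife needs >= 3 non-empty {block_days}-day blocks; "
            f"got {len(blocks)}"
        )
    reps = []
    for b in blocks:
        reps.append(np.asarray(estimator(gbi.subset_rows(block != b)), dtype=float))
    reps = np.array(reps)
    bc = len(blocks)
    se = np.sqrt((bc - 1) / bc * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    return se, reps
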