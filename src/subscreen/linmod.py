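"""Per-clone dye-swap linear models with empirical-Bayes moderation.

Each clone's log-ratio is estimated across replicate arrays of one
contrast: observations are sign-corrected for dye orientation
(y_i = orientation_i * M_i) and combined by weighted mean.  Gene-wise
residual variances are shrunk toward a pooled prior estimated by
method-of-moments on log variances; the resulting moderated t has
d0 + d degrees of freedom.  Significance is adjusted by the
Benjamini-Hochberg step-up, and the B-statistic reports the posterior
log-odds of differential expression with a configurable prior
proportion of changed clones (default 0.5 — half the clones of an SSH
library are expected to be real).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "GeneFit",
    "PriorEstimate",
    "GeneStats",
    "fit_dye_swap",
    "estimate_s2_prior",
    "trigamma_inverse",
    "estimate_v0",
    "moderated_stats",
    "bh_adjust",
    "ebayes",
]

log = logging.getLogger(__name__)


@dataclass
class GeneFit:
    """Per-clone effect estimates from the dye-swap linear model."""

    clone_ids: np.ndarray
    beta: np.ndarray  # estimated log2 ratio
    stdev_unscaled: np.ndarray  # sqrt(v) with var(beta) = v * sigma^2
    s2: np.ndarray  # residual variance, NaN when df_residual == 0
    df_residual: np.ndarray
    amean: np.ndarray


@dataclass
class PriorEstimate:
    """Empirical-Bayes hyperparameters shared across clones."""

    d0: float  # prior degrees of freedom, may be inf
    s0_2: float  # prior variance
    v0: float = 0.0  # variance of true log-ratios of changed clones
    prior_p: float = 0.5

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_2 > 0:
            raise ValueError("s0_2 must be positive")
        if not 0 < self.prior_p < 1:
            raise ValueError("prior_p must be in (0, 1)")


@dataclass
class GeneStats:
    """Moderated statistics per clone."""

    t_mod: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray
    b_stat: np.ndarray
    s2_post: np.ndarray
    df_total: np.ndarray


# ---------------------------------------------------------------------------
# Linear model


def fit_dye_swap(
    m: np.ndarray,
    orientations: np.ndarray,
    weights: np.ndarray | None = None,
    amean: np.ndarray | None = None,
    clone_ids: np.ndarray | None = None,
) -> GeneFit:
    """Fit the single-coefficient dye-swap model per clone.

    Parameters
    ----------
    m : (n_clones, n_arrays) matrix of normalized M values.
    orientations : per-array +1/-1 dye orientation relative to the
        contrast's numerator sample.
    weights : (n_clones, n_arrays) nonnegative observation weights;
        zero removes the observation.

    For each clone, beta is the weighted mean of the sign-corrected
    values, s2 the weighted residual variance on d = (#used - 1) degrees
    of freedom, and stdev_unscaled = 1/sqrt(sum of weights).  Clones with
    a single usable observation carry s2 = NaN, d = 0; clones with none
    carry beta = NaN.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("m must be 2-D (clones x arrays)")
    orientations = np.asarray(orientations, dtype=float)
    if orientations.shape != (m.shape[1],):
        raise ValueError("one orientation per array required")
    if weights is None:
        weights = np.ones_like(m)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != m.shape:
        raise ValueError("weights must match m")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")

    y = m * orientations[np.newaxis, :]
    w = np.where(np.isfinite(y), weights, 0.0)
    y = np.where(w > 0, y, 0.0)

    wsum = w.sum(axis=1)
    nused = (w > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(wsum > 0, (w * y).sum(axis=1) / wsum, np.nan)
        resid2 = w * (y - beta[:, np.newaxis]) ** 2
        df = np.maximum(nused - 1, 0)
        s2 = np.where(df > 0, resid2.sum(axis=1) / df, np.nan)
        su = np.where(wsum > 0, 1.0 / np.sqrt(wsum), np.nan)

    n = m.shape[0]
    if clone_ids is None:
        clone_ids = np.asarray([f"clone{i}" for i in range(n)], dtype=object)
    if amean is None:
        amean = np.full(n, np.nan)
    nflag = int((wsum == 0).sum())
    if nflag:
        log.info("%d clones with no usable observation (beta = NaN)", nflag)
    return GeneFit(
        clone_ids=np.asarray(clone_ids, dtype=object),
        beta=beta,
        stdev_unscaled=su,
        s2=s2,
        df_residual=df.astype(float),
        amean=np.asarray(amean, dtype=float),
    )


# ---------------------------------------------------------------------------
# Hyperparameter estimation


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_s2_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0^2).

    Works on e_g = log s2_g - digamma(df_g/2) + log(df_g/2), whose mean
    and excess spread over the trigamma term identify the prior.  A
    non-positive excess means no evidence of variance heterogeneity:
    d0 = inf and s0^2 = exp(mean e).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df >= 1)
    if ok.sum() < 2:
        raise ValueError("need at least 2 clones with positive df to estimate the prior")
    pos = ok & (s2 > 0)
    if pos.sum() < 2:
        # degenerate (e.g. exactly replicated observations): no spread to model
        log.warning("fewer than 2 positive residual variances; prior is pinned")
        return np.inf, float(max(np.mean(s2[ok]), 1e-15))
    s2, df = s2[pos], df[pos]
    G = s2.size
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    rhs = np.mean((e - ebar) ** 2 * G / (G - 1) - special.polygamma(1, df / 2.0))
    if rhs <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_2 = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def estimate_v0(
    t_mod: np.ndarray,
    stdev_unscaled: np.ndarray,
    df_total: np.ndarray,
    prior_p: float = 0.5,
    v_floor_factor: float = 0.1,
) -> float:
    """Estimate the variance of true log-ratios among changed clones.

    Moment-matches the top ``prior_p * G / 2`` absolute moderated-t values
    against their expected quantiles under the scaled-t alternative, then
    averages the implied variance inflation.  Floored at
    ``v_floor_factor`` times the mean unscaled variance so the B-statistic
    stays finite on null data.  The choice of v0 never changes the t
    ranking — only B values move.
    """
    t = np.abs(np.asarray(t_mod, dtype=float))
    v1 = np.asarray(stdev_unscaled, dtype=float) ** 2
    df = np.asarray(df_total, dtype=float)
    ok = np.isfinite(t) & np.isfinite(v1)
    t, v1, df = t[ok], v1[ok], df[ok]
    df = np.minimum(np.nan_to_num(df, posinf=1e6), 1e6)  # t(1e6) ~ normal
    G = t.size
    floor = v_floor_factor * float(np.mean(v1)) if G else 0.0
    ntarget = int(np.ceil(prior_p / 2.0 * G))
    if ntarget < 10:
        log.warning("too few clones for v0 moment matching; using the floor")
        return floor if floor > 0 else v_floor_factor
    p = max(ntarget / G, prior_p)
    # put all t on a common df scale via tail-probability matching
    maxdf = np.max(df)
    smaller = df < maxdf
    if np.any(smaller):
        tail = stats.t.logsf(t[smaller], df[smaller])
        t = t.copy()
        t[smaller] = stats.t.isf(np.exp(tail), maxdf)
    order = np.argsort(t)[::-1][:ntarget]
    tt, vv = t[order], v1[order]
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, maxdf)
    ptarget = ((r - 0.5) / G - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if np.any(pos):
        qtarget = stats.t.isf(ptarget[pos] / 2.0, maxdf)
        v0[pos] = vv[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    est = float(np.mean(np.maximum(v0, 0.0)))
    return max(est, floor)


# ---------------------------------------------------------------------------
# Moderated statistics


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the size of the testing universe and may exceed ``len(p)``
    (e.g. when some clones were filtered but still count as tests).
    NaNs pass through untouched.
    """
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    vals = p[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = vals.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("universe m cannot be smaller than the number of p-values")
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, k + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(k)
    adj[order] = q
    out = np.full(p.shape, np.nan)
    out[ok] = adj
    return out


def moderated_stats(
    fit: GeneFit,
    prior: PriorEstimate,
    n_tests: int | None = None,
    subset: np.ndarray | None = None,
) -> GeneStats:
    """Moderated t, p, BH-adjusted p and B-statistic for every clone.

    The posterior variance s2_post = (d0*s0^2 + d*s2)/(d0 + d) shrinks
    each clone's variance toward the prior; clones with d = 0 land exactly
    on the prior.  p-values come from Student t with d0 + d degrees of
    freedom (normal when d0 = inf).  The B-statistic is the log posterior
    odds of differential expression; B = 0 means a 50-50 chance.

    ``subset`` restricts the BH adjustment (and its default universe) to
    a boolean mask of clones, e.g. the clones of one library.
    """
    d0, s0_2, v0, prior_p = prior.d0, prior.s0_2, prior.v0, prior.prior_p
    d = fit.df_residual
    s2 = np.where(d > 0, fit.s2, 0.0)
    if np.isinf(d0):
        s2_post = np.full_like(fit.beta, s0_2)
        df_total = np.full_like(fit.beta, np.inf)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta / (fit.stdev_unscaled * np.sqrt(s2_post))
    usable = np.isfinite(t)

    p = np.full_like(t, np.nan)
    if np.isinf(d0):
        p[usable] = 2.0 * stats.norm.sf(np.abs(t[usable]))
    else:
        p[usable] = 2.0 * stats.t.sf(np.abs(t[usable]), df_total[usable])

    if subset is None:
        subset = np.ones(t.shape, dtype=bool)
    adj = np.full_like(t, np.nan)
    in_bh = subset & usable
    m_bh = n_tests if n_tests is not None else int(in_bh.sum())
    adj[in_bh] = bh_adjust(p[in_bh], m=m_bh)

    v = fit.stdev_unscaled**2
    r = v / (v + v0) if v0 > 0 else np.ones_like(v)
    odds = prior_p / (1.0 - prior_p)
    b = np.full_like(t, np.nan)
    if np.isinf(d0):
        # nu -> inf limit of the scaled-t odds ratio
        b[usable] = (
            np.log(odds)
            + 0.5 * np.log(r[usable])
            + 0.5 * t[usable] ** 2 * (1.0 - r[usable])
        )
    else:
        nu = df_total
        t2 = t**2
        with np.errstate(divide="ignore", invalid="ignore"):
            kernel = ((t2 + nu) / (t2 * r + nu)) ** ((1.0 + nu) / 2.0)
            b_all = np.log(odds * np.sqrt(r) * kernel)
        b[usable] = b_all[usable]

    return GeneStats(
        t_mod=t, p_value=p, adj_p=adj, b_stat=b, s2_post=s2_post, df_total=df_total
    )


def ebayes(
    fit: GeneFit,
    prior_p: float = 0.5,
    n_tests: int | None = None,
    subset: np.ndarray | None = None,
) -> tuple[GeneStats, PriorEstimate]:
    """Full empirical-Bayes pass: prior, v0 and moderated statistics."""
    d0, s0_2 = estimate_s2_prior(fit.s2, fit.df_residual)
    prior = PriorEstimate(d0=d0, s0_2=s0_2, v0=0.0, prior_p=prior_p)
    stats0 = moderated_stats(fit, prior, n_tests=n_tests, subset=subset)
    prior.v0 = estimate_v0(
        stats0.t_mod, fit.stdev_unscaled, stats0.df_total, prior_p=prior_p
    )
    return moderated_stats(fit, prior, n_tests=n_tests, subset=subset), prior
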