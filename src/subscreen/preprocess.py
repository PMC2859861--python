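"""Pre-processing for two-colour SSH-library arrays.

The screening arrays carry probes *selected* for differential expression,
so the usual loess assumption (most spots unchanged) fails.  Normalization
therefore leans entirely on the alien spike-in control spots, which were
hybridised at identical mass in both channels and hence have a true
log-ratio of zero:

1. spot quality weights (0/1) from GenePix flags and per-channel
   signal-to-noise ratios;
2. normexp background correction per array-channel with an intensity
   offset (default 50) that damps log-ratio variance at low intensity;
3. M = log2(Cy5/Cy3), A = (log2 Cy5 + log2 Cy3)/2 per spot;
4. within-array print-tip loess of M on A fitted through control spots
   only (library spots get zero weight in the fit);
5. between-array Aquantile normalization of the A values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

from .arrays import ArraySpots

__all__ = [
    "MAset",
    "NormexpConfig",
    "LoessConfig",
    "compute_spot_weights",
    "normexp_fit",
    "normexp_correct",
    "compute_ma",
    "build_ma",
    "normalize_within_control_loess",
    "normalize_between_aquantile",
]

log = logging.getLogger(__name__)

CONTROL_ROLES = ("control_gfp", "control_globin", "control_nptii", "control_its")


@dataclass
class NormexpConfig:
    """Settings for normal+exponential background correction."""

    offset: float = 50.0
    estimator: str = "mle"  # or "moments"

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class LoessConfig:
    """Settings for the control-spot print-tip loess of M on A."""

    span: float = 0.3
    robust_iterations: int = 4
    min_controls: int = 10
    #: weight given to library spots in the curve fit; 0 = controls only
    clone_weight: float = 0.0

    def __post_init__(self):
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")


@dataclass
class MAset:
    """Per-spot M/A values, weights and metadata for one or more arrays.

    ``m``/``a``/``weights`` are (n_spots, n_arrays) matrices in identical
    spot order across arrays; ``roles`` and ``printtip`` are per-spot.
    """

    m: np.ndarray
    a: np.ndarray
    weights: np.ndarray
    clone_ids: np.ndarray
    roles: np.ndarray
    printtip: np.ndarray
    array_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.m = np.atleast_2d(np.asarray(self.m, dtype=float).T).T
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float).T).T
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float).T).T
        if not (self.m.shape == self.a.shape == self.weights.shape):
            raise ValueError("m, a and weights must share dimensions")

    @property
    def n_arrays(self) -> int:
        return self.m.shape[1]

    @property
    def is_control(self) -> np.ndarray:
        return np.isin(self.roles, CONTROL_ROLES)

    def copy(self) -> "MAset":
        return MAset(
            m=self.m.copy(),
            a=self.a.copy(),
            weights=self.weights.copy(),
            clone_ids=self.clone_ids.copy(),
            roles=self.roles.copy(),
            printtip=self.printtip.copy(),
            array_ids=list(self.array_ids),
        )


# ---------------------------------------------------------------------------
# Spot weights


def compute_spot_weights(spots: ArraySpots, snr_threshold: float = 3.0) -> np.ndarray:
    """0/1 quality weight per spot.

    A spot is excluded (weight 0) when its GenePix flag is negative or
    when either channel's signal-to-noise ratio is below ``snr_threshold``.
    The weights exclude spots both from normalization-curve fitting and
    from the linear-model fit downstream.
    """
    df = spots.spots
    snr = np.minimum(df["snr_cy3"].to_numpy(float), df["snr_cy5"].to_numpy(float))
    bad = (df["flag"].to_numpy() < 0) | ~np.isfinite(snr) | (snr < snr_threshold)
    return (~bad).astype(float)


# ---------------------------------------------------------------------------
# normexp background correction


def _normexp_m2loglik(par, x):
    """-2 log-likelihood of x = B + S, B ~ N(mu, s2), S ~ Exp(alpha)."""
    mu, log_sigma, log_alpha = par
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    mu_sf = x - mu - sigma**2 / alpha
    # log density of the exp+normal convolution
    logf = (
        -np.log(alpha)
        + (sigma**2 / (2 * alpha**2))
        - (x - mu) / alpha
        + stats.norm.logcdf(mu_sf / sigma)
    )
    return -2.0 * np.sum(logf)


def _moments_start(x):
    mu = np.quantile(x, 0.03)
    bg = x[x < np.quantile(x, 0.1)]
    sigma = max(np.std(bg), 1e-2) if bg.size > 1 else max(np.std(x) / 10, 1e-2)
    alpha = max(np.mean(x) - mu, 1e-2)
    return mu, sigma, alpha


def normexp_fit(x: np.ndarray, estimator: str = "mle") -> tuple[float, float, float]:
    """Fit (mu, sigma, alpha) of the normal+exponential convolution.

    Maximizes the exact log-likelihood by Nelder-Mead from a moments-based
    start (``estimator='moments'`` returns the start itself).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite intensities to fit normexp")
    mu0, sigma0, alpha0 = _moments_start(x)
    if estimator == "moments":
        return mu0, sigma0, alpha0
    res = optimize.minimize(
        _normexp_m2loglik,
        x0=[mu0, np.log(sigma0), np.log(alpha0)],
        args=(x,),
        method="Nelder-Mead",
        options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-4},
    )
    mu, log_sigma, log_alpha = res.x
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))


def normexp_signal(params, x) -> np.ndarray:
    """Posterior mean E[S | x] of the signal under the normexp model.

    With mu_s = x - mu - sigma^2/alpha, E[S|x] = mu_s + sigma *
    phi(mu_s/sigma) / Phi(mu_s/sigma); computed with log-scale normal
    functions so the Mills ratio stays stable far in the left tail.
    """
    mu, sigma, alpha = params
    x = np.asarray(x, dtype=float)
    mu_s = x - mu - sigma**2 / alpha
    z = mu_s / sigma
    mills = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    out = mu_s + sigma * mills
    # the conditional mean of a positive variable is positive
    return np.maximum(out, 1e-10)


def normexp_correct(net: np.ndarray, cfg: NormexpConfig | None = None) -> np.ndarray:
    """Background-correct one array-channel of net intensities.

    ``net`` is foreground median minus background median per spot (may be
    negative).  Returns E[S|x] + offset, strictly positive and monotone
    non-decreasing in the input.  A degenerate fit falls back to
    max(net, small) + offset with a logged warning.
    """
    if cfg is None:
        cfg = NormexpConfig()
    net = np.asarray(net, dtype=float)
    finite = net[np.isfinite(net)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite intensities")
    try:
        mu, sigma, alpha = normexp_fit(net, estimator=cfg.estimator)
        degenerate = sigma < 1e-6 or alpha < 1e-6 or not np.isfinite(mu)
    except (ValueError, FloatingPointError):
        degenerate = True
    if degenerate:
        log.warning("degenerate normexp fit; falling back to thresholded intensities")
        return np.maximum(net, 0.5) + cfg.offset
    return normexp_signal((mu, sigma, alpha), net) + cfg.offset


# ---------------------------------------------------------------------------
# M/A computation


def compute_ma(cy5: np.ndarray, cy3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """M = log2(cy5/cy3) and A = (log2 cy5 + log2 cy3)/2 per spot."""
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if np.any(cy5 <= 0) or np.any(cy3 <= 0):
        raise ValueError("intensities must be positive (background-correct first)")
    l5, l3 = np.log2(cy5), np.log2(cy3)
    return l5 - l3, (l5 + l3) / 2.0


def build_ma(
    spots: ArraySpots,
    roles: np.ndarray,
    snr_threshold: float = 3.0,
    normexp: NormexpConfig | None = None,
) -> MAset:
    """Weights + background correction + M/A for a single array."""
    df = spots.spots
    w = compute_spot_weights(spots, snr_threshold=snr_threshold)
    cy5 = normexp_correct(df["fg_cy5"].to_numpy(float) - df["bg_cy5"].to_numpy(float), normexp)
    cy3 = normexp_correct(df["fg_cy3"].to_numpy(float) - df["bg_cy3"].to_numpy(float), normexp)
    m, a = compute_ma(cy5, cy3)
    return MAset(
        m=m,
        a=a,
        weights=w,
        clone_ids=df["clone_id"].to_numpy(dtype=object),
        roles=np.asarray(roles, dtype=object),
        printtip=df["block"].to_numpy(int),
        array_ids=[spots.array_id],
    )


# ---------------------------------------------------------------------------
# Within-array control-spot loess


def _control_loess_fit(a, m, fit_mask, eval_a, cfg: LoessConfig) -> np.ndarray:
    """Robust local-linear loess of M on A over ``fit_mask`` spots,
    evaluated at ``eval_a`` with constant extrapolation beyond the
    controls' A-range."""
    ax, mx = a[fit_mask], m[fit_mask]
    n = ax.size
    frac = min(1.0, max(cfg.span, 10.0 / n))
    fitted = sm.nonparametric.lowess(
        mx, ax, frac=frac, it=cfg.robust_iterations, return_sorted=True
    )
    # np.interp clamps outside the fitted range: boundary value held constant
    return np.interp(eval_a, fitted[:, 0], fitted[:, 1])


def normalize_within_control_loess(ma: MAset, cfg: LoessConfig | None = None) -> MAset:
    """Subtract a control-spot loess curve of M on A, per print-tip group.

    Only control spots (full weight) enter the curve fit — library spots
    get ``cfg.clone_weight`` (default zero, i.e. excluded) — intersected
    with the quality weights.  Groups with fewer than ``cfg.min_controls``
    usable controls fall back to a whole-array control loess.  Weight-0
    spots are still normalized; they just never influence the curve.
    """
    if cfg is None:
        cfg = LoessConfig()
    if ma.n_arrays != 1:
        raise ValueError("normalize one array at a time")
    out = ma.copy()
    a = ma.a[:, 0]
    m = ma.m[:, 0]
    w = ma.weights[:, 0]
    usable = (w > 0) & np.isfinite(a) & np.isfinite(m)
    usable_ctrl = ma.is_control & usable
    if cfg.clone_weight > 0:
        # partial-weight variant: a deterministic 1-in-round(1/clone_weight)
        # thinning of library spots joins the controls in the curve fit
        step = max(1, int(round(1.0 / cfg.clone_weight)))
        lib = np.flatnonzero(usable & ~ma.is_control)
        thin = np.zeros_like(usable_ctrl)
        thin[lib[::step]] = True
        usable_ctrl = usable_ctrl | thin
    if usable_ctrl.sum() == 0:
        raise ValueError(
            "no usable control spots on the array; use a global loess or skip normalization"
        )
    correction = np.zeros_like(m)
    global_fit = None
    for tip in np.unique(ma.printtip):
        grp = ma.printtip == tip
        ctrl = grp & usable_ctrl
        need = max(cfg.min_controls, int(np.ceil(cfg.span * ctrl.sum())))
        if ctrl.sum() >= need:
            correction[grp] = _control_loess_fit(a, m, ctrl, a[grp], cfg)
        else:
            if global_fit is None:
                global_fit = _control_loess_fit(a, m, usable_ctrl, a, cfg)
                log.info(
                    "print-tip group(s) with < %d usable controls: using array-wide control loess",
                    cfg.min_controls,
                )
            correction[grp] = global_fit[grp]
    out.m[:, 0] = m - correction
    return out


# ---------------------------------------------------------------------------
# Between-array Aquantile


def normalize_between_aquantile(sets: list[MAset] | MAset) -> MAset:
    """Quantile-normalize A values across arrays; M untouched.

    Each array's sorted A column is replaced by the across-array mean of
    sorted A at that rank; tied A values within an array receive the mean
    of the reference values over their tied ranks, making the result
    deterministic and permutation-invariant.
    """
    if isinstance(sets, MAset):
        combined = sets.copy()
    else:
        first = sets[0]
        for s in sets[1:]:
            if not np.array_equal(s.clone_ids, first.clone_ids):
                raise ValueError("arrays must share an identical spot order")
        combined = MAset(
            m=np.column_stack([s.m[:, 0] for s in sets]),
            a=np.column_stack([s.a[:, 0] for s in sets]),
            weights=np.column_stack([s.weights[:, 0] for s in sets]),
            clone_ids=first.clone_ids.copy(),
            roles=first.roles.copy(),
            printtip=first.printtip.copy(),
            array_ids=[s.array_ids[0] for s in sets],
        )
    if combined.n_arrays == 1:
        log.info("single array: Aquantile is a no-op")
        return combined
    a = combined.a
    ref = np.mean(np.sort(a, axis=0), axis=1)
    newa = np.empty_like(a)
    n = a.shape[0]
    for j in range(a.shape[1]):
        order = np.argsort(a[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = ref
        # ties share the mean of their ranks' reference values
        uniq, inverse = np.unique(a[:, j], return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inverse, weights=col)
            counts = np.bincount(inverse)
            col = (sums / counts)[inverse]
        newa[:, j] = col
    combined.a = newa
    return combined
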