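"""End-to-end screening pipeline: files in, top tables out.

Chains the stages: read design + arrays, spot weights, background
correction, within-array control-spot loess, between-array Aquantile,
duplicate-spot collapse, per-contrast dye-swap linear models with
empirical-Bayes moderation, and library top tables with quadrant labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arrays as aio
from . import enrichment, linmod, preprocess

__all__ = ["ScreenConfig", "ScreenResult", "screen", "collapse_duplicates"]

log = logging.getLogger(__name__)

LIB_ROLES = {"forward": "forward_library", "reverse": "reverse_library"}


@dataclass
class ScreenConfig:
    """Tunable parameters of a screening run (defaults as published)."""

    snr_threshold: float = 3.0
    background: str = "normexp"  # "normexp" | "subtract" | "none"
    normexp: preprocess.NormexpConfig = field(default_factory=preprocess.NormexpConfig)
    loess: preprocess.LoessConfig = field(default_factory=preprocess.LoessConfig)
    prior_p: float = 0.5
    alpha: float = 0.05
    top_n: int = 300
    library_mode: str = "both"
    #: override of the BH universe per library, e.g. {"forward": 2146}
    bh_universe: dict = field(default_factory=dict)


@dataclass
class ScreenResult:
    top_tables: dict  # library -> primary (ER3) top table
    er2_tables: dict  # library -> secondary (ER2 contrast) top table
    priors: dict  # contrast -> PriorEstimate
    ma_norm: preprocess.MAset
    ma_raw: preprocess.MAset
    summaries: dict = field(default_factory=dict)
    design: aio.ExperimentDesign | None = None


def _background_correct(arr: aio.ArraySpots, cfg: ScreenConfig):
    df = arr.spots
    net5 = df["fg_cy5"].to_numpy(float) - df["bg_cy5"].to_numpy(float)
    net3 = df["fg_cy3"].to_numpy(float) - df["bg_cy3"].to_numpy(float)
    if cfg.background == "normexp":
        cy5 = preprocess.normexp_correct(net5, cfg.normexp)
        cy3 = preprocess.normexp_correct(net3, cfg.normexp)
    elif cfg.background == "subtract":
        off = cfg.normexp.offset
        cy5 = np.maximum(net5 + off, 0.5)
        cy3 = np.maximum(net3 + off, 0.5)
    elif cfg.background == "none":
        cy5 = np.maximum(df["fg_cy5"].to_numpy(float), 0.5)
        cy3 = np.maximum(df["fg_cy3"].to_numpy(float), 0.5)
    else:
        raise ValueError(f"unknown background method {cfg.background!r}")
    return cy5, cy3


def _load_and_preprocess(
    bundle_dir: Path, design: aio.ExperimentDesign, cfg: ScreenConfig
) -> tuple[preprocess.MAset, preprocess.MAset]:
    """Read every array, weight, correct, compute M/A, loess, Aquantile.

    Returns (raw, normalized) multi-array M/A sets in Targets order.
    """
    per_array_raw = []
    per_array_norm = []
    for _, trow in design.targets.iterrows():
        path = bundle_dir / trow["filename"]
        arr = aio.read_gpr(path, layout=design.layout, array_id=trow["array_id"])
        roles = design.assign_roles(arr.spots["clone_id"], arr.spots["name"])
        w = preprocess.compute_spot_weights(arr, snr_threshold=cfg.snr_threshold)
        cy5, cy3 = _background_correct(arr, cfg)
        m, a = preprocess.compute_ma(cy5, cy3)
        ma = preprocess.MAset(
            m=m,
            a=a,
            weights=w,
            clone_ids=arr.spots["clone_id"].to_numpy(object),
            roles=roles,
            printtip=arr.spots["block"].to_numpy(int),
            array_ids=[arr.array_id],
        )
        per_array_raw.append(ma)
        per_array_norm.append(preprocess.normalize_within_control_loess(ma, cfg.loess))
    # the raw set keeps unnormalized M and A for diagnostics
    raw = preprocess.MAset(
        m=np.column_stack([s.m[:, 0] for s in per_array_raw]),
        a=np.column_stack([s.a[:, 0] for s in per_array_raw]),
        weights=np.column_stack([s.weights[:, 0] for s in per_array_raw]),
        clone_ids=per_array_raw[0].clone_ids,
        roles=per_array_raw[0].roles,
        printtip=per_array_raw[0].printtip,
        array_ids=[s.array_ids[0] for s in per_array_raw],
    )
    norm = preprocess.normalize_between_aquantile(per_array_norm)
    return raw, norm


def collapse_duplicates(ma: preprocess.MAset) -> dict:
    """Average the within-array duplicate spots of each library clone.

    Returns per-clone matrices (clones x arrays): weighted-mean M,
    mean A, summed weight, plus clone ids, library labels and the roles
    they came from.  Spots whose duplicates are all weight-0 keep weight
    0 (their unweighted mean M is carried for completeness).
    """
    lib_mask = np.isin(ma.roles, list(LIB_ROLES.values()))
    ids = ma.clone_ids[lib_mask]
    roles = ma.roles[lib_mask]
    m = ma.m[lib_mask]
    a = ma.a[lib_mask]
    w = ma.weights[lib_mask]

    frame = pd.DataFrame({"clone_id": ids, "role": roles})
    order = frame.groupby("clone_id", sort=True)
    clone_ids = np.array(list(order.groups.keys()), dtype=object)
    idx_lists = [np.asarray(v) for v in order.groups.values()]

    n_c, n_arr = len(clone_ids), m.shape[1]
    mm = np.full((n_c, n_arr), np.nan)
    aa = np.full((n_c, n_arr), np.nan)
    ww = np.zeros((n_c, n_arr))
    lib = np.empty(n_c, dtype=object)
    for i, idx in enumerate(idx_lists):
        wi = w[idx]
        mi = m[idx]
        ai = a[idx]
        wsum = wi.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_w = np.where(wsum > 0, (wi * mi).sum(axis=0) / wsum, mi.mean(axis=0))
        mm[i] = mean_w
        aa[i] = ai.mean(axis=0)
        ww[i] = wsum
        lib[i] = "forward" if roles[idx[0]] == "forward_library" else "reverse"
    return {
        "clone_ids": clone_ids,
        "m": mm,
        "a": aa,
        "weights": ww,
        "library": lib,
    }


def _contrast_fit(
    collapsed: dict,
    design: aio.ExperimentDesign,
    contrast: str,
    sign_flip: np.ndarray | None = None,
) -> linmod.GeneFit | None:
    """Dye-swap fit of one contrast over its arrays; None if absent."""
    sub = design.arrays_for(contrast)
    if len(sub) == 0:
        return None
    cols = [list(design.targets["array_id"]).index(a) for a in sub["array_id"]]
    m = collapsed["m"][:, cols]
    w = collapsed["weights"][:, cols]
    a = collapsed["a"][:, cols]
    orient = sub["orientation"].to_numpy(float)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        amean = np.nanmean(np.where(w > 0, a, np.nan), axis=1)
    fit = linmod.fit_dye_swap(
        m, orient, weights=w, amean=amean, clone_ids=collapsed["clone_ids"]
    )
    if sign_flip is not None:
        fit.beta = fit.beta * sign_flip
    return fit


def screen(bundle_dir, cfg: ScreenConfig | None = None,
           targets="targets.tsv", spottypes="spottypes.tsv", gal="layout.gal") -> ScreenResult:
    """Run the full screen on a bundle directory.

    The directory must hold the Targets, SpotTypes and GAL files (names
    configurable) and every GPR file the Targets table references.
    """
    if cfg is None:
        cfg = ScreenConfig()
    bundle_dir = Path(bundle_dir)
    for f, label in ((targets, "Targets"), (spottypes, "SpotTypes"), (gal, "GAL")):
        if not (bundle_dir / f).exists():
            raise FileNotFoundError(f"{label} file not found: {bundle_dir / f}")
    design = aio.read_design(
        bundle_dir / targets, bundle_dir / spottypes, bundle_dir / gal,
        library_mode=cfg.library_mode,
    )
    raw, norm = _load_and_preprocess(bundle_dir, design, cfg)
    collapsed = collapse_duplicates(norm)
    lib = collapsed["library"]

    libraries = {"both": ("forward", "reverse"), "forward": ("forward",),
                 "reverse": ("reverse",)}[cfg.library_mode]

    # canonical ER3 fit is log2(UT/UC); the reverse library reports log2(UC/UT)
    flip = np.where(lib == "reverse", -1.0, 1.0)
    er3_fit = _contrast_fit(collapsed, design, "er3", sign_flip=flip)
    if er3_fit is None:
        raise aio.DesignError("no arrays for the differential-expression (UT vs UC) contrast")
    er2_fits = {
        "forward": _contrast_fit(collapsed, design, "er2_forward"),
        "reverse": _contrast_fit(collapsed, design, "er2_reverse"),
    }

    er3_stats, er3_prior = linmod.ebayes(er3_fit, prior_p=cfg.prior_p)
    priors = {"er3": er3_prior}
    usable = np.isfinite(er3_stats.p_value)
    for library in libraries:
        mask = (lib == library) & usable
        m_bh = cfg.bh_universe.get(library, int(mask.sum()))
        er3_stats.adj_p[mask] = linmod.bh_adjust(er3_stats.p_value[mask], m=m_bh)
    log.info("ER3 prior: d0=%.4g s0^2=%.4g v0=%.4g", er3_prior.d0, er3_prior.s0_2,
             er3_prior.v0)

    top_tables: dict[str, pd.DataFrame] = {}
    er2_tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    for library in libraries:
        mask = lib == library
        er2_fit = er2_fits[library]
        table = enrichment.build_top_table(
            er3_fit, er3_stats, er2_fit, library, mask=mask
        )
        top_tables[library] = table
        summaries[library] = enrichment.export_er_plot(
            table, path=None, top_n=cfg.top_n, alpha=cfg.alpha
        )
        if er2_fit is not None:
            sub = mask
            e2_stats, e2_prior = linmod.ebayes(
                _subset_fit(er2_fit, sub), prior_p=cfg.prior_p
            )
            priors[f"er2_{library}"] = e2_prior
            er2_tables[library] = _er2_table(_subset_fit(er2_fit, sub), e2_stats, library)

    return ScreenResult(
        top_tables=top_tables,
        er2_tables=er2_tables,
        priors=priors,
        ma_norm=norm,
        ma_raw=raw,
        summaries=summaries,
        design=design,
    )


def _subset_fit(fit: linmod.GeneFit, mask: np.ndarray) -> linmod.GeneFit:
    return linmod.GeneFit(
        clone_ids=fit.clone_ids[mask],
        beta=fit.beta[mask],
        stdev_unscaled=fit.stdev_unscaled[mask],
        s2=fit.s2[mask],
        df_residual=fit.df_residual[mask],
        amean=fit.amean[mask],
    )


def _er2_table(fit: linmod.GeneFit, stats: linmod.GeneStats, library: str) -> pd.DataFrame:
    """Secondary top table: the subtraction contrast's own statistics."""
    df = pd.DataFrame(
        {
            "ID": fit.clone_ids,
            "logFC(invER2)": fit.beta,
            "AveExpr": fit.amean,
            "t": stats.t_mod,
            "P.Value": stats.p_value,
            "adj.P.Val": stats.adj_p,
            "B": stats.b_stat,
        }
    )
    df["library"] = library
    return df.sort_values(
        by=["P.Value", "t", "ID"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "t" else col,
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
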