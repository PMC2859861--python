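"""Enrichment-ratio top tables, quadrant classification and ER plots.

Two enrichment ratios summarise each library clone:

* **ER3** — log2(UT/UC) for forward-library clones, log2(UC/UT) for
  reverse-library clones: the treatment effect on transcript abundance
  (positive = enriched in the library's tester sample).
* **inverse ER2** — log2(UT/ST) forward, log2(UC/SC) reverse: negative
  values flag transcripts that were *rare* before subtraction and were
  boosted by the SSH procedure.

The primary top table carries the ER3 statistics (moderated t, p,
BH-adjusted p, B) next to the inverse-ER2 estimate; a secondary table
reports the ER2 contrast's own statistics.  Clones are classified into
the four quadrants of the ER plot (Up/Down x Rare/Abundant).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .linmod import GeneFit, GeneStats

__all__ = [
    "TOP_TABLE_COLUMNS",
    "build_top_table",
    "classify_quadrant",
    "fold_change",
    "write_top_table",
    "export_er_plot",
]

log = logging.getLogger(__name__)

#: The eight published columns, in order, plus the appended quadrant/library.
TOP_TABLE_COLUMNS = [
    "ID",
    "logFC(ER3)",
    "AveExpr",
    "t",
    "P.Value",
    "adj.P.Val",
    "B",
    "invER2",
    "quadrant",
    "library",
]

# forward-library quadrants by (sign of ER3, sign of invER2); zero counts
# as positive so every finite pair gets a deterministic label
_FORWARD_QUADRANT = {
    (True, False): "Up.Rare",
    (True, True): "Up.Abundant",
    (False, True): "Down.Rare",
    (False, False): "Down.Abundant",
}
# relabelling the library flips the Up/Down half of the name
_FLIP = {
    "Up.Rare": "Down.Rare",
    "Up.Abundant": "Down.Abundant",
    "Down.Rare": "Up.Rare",
    "Down.Abundant": "Up.Abundant",
}


def classify_quadrant(er3: float, inv_er2: float, library: str = "forward") -> str:
    """Quadrant label for one clone.

    Forward library: ER3 > 0 with invER2 < 0 means up-regulated by the
    treatment and rare before subtraction (quadrant 1).  For the reverse
    library, whose ER3 measures down-regulation, the Up/Down half of each
    label is flipped.  Zeros join the positive side; NaN in either axis
    gives "Unclassified".
    """
    if not (np.isfinite(er3) and np.isfinite(inv_er2)):
        return "Unclassified"
    label = _FORWARD_QUADRANT[(er3 >= 0, inv_er2 >= 0)]
    if library == "reverse":
        label = _FLIP[label]
    elif library != "forward":
        raise ValueError(f"library must be forward or reverse, got {library!r}")
    return label


def fold_change(logfc: float | np.ndarray) -> float | np.ndarray:
    """Linear fold change 2**logfc of a log2 ratio."""
    return np.power(2.0, logfc)


def build_top_table(
    er3_fit: GeneFit,
    er3_stats: GeneStats,
    er2_fit: GeneFit | None,
    library: str,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the primary top table for one library.

    ER3 statistics columns come from the differential-expression contrast;
    the invER2 column carries the subtraction contrast's effect estimate
    (NaN with a logged warning count where the clone was not fitted
    there).  Rows are sorted by p ascending, ties broken by \\|t\\|
    descending then clone id.
    """
    if mask is None:
        mask = np.ones(er3_fit.beta.shape, dtype=bool)
    ids = er3_fit.clone_ids[mask]
    df = pd.DataFrame(
        {
            "ID": ids,
            "logFC(ER3)": er3_fit.beta[mask],
            "AveExpr": er3_fit.amean[mask],
            "t": er3_stats.t_mod[mask],
            "P.Value": er3_stats.p_value[mask],
            "adj.P.Val": er3_stats.adj_p[mask],
            "B": er3_stats.b_stat[mask],
        }
    )
    if er2_fit is not None:
        lookup = pd.Series(er2_fit.beta, index=er2_fit.clone_ids)
        df["invER2"] = lookup.reindex(df["ID"]).to_numpy(dtype=float)
        missing = int(df["invER2"].isna().sum())
        if missing:
            log.warning(
                "%d %s-library clones missing from the ER2 contrast (invER2 = NaN)",
                missing,
                library,
            )
    else:
        df["invER2"] = np.nan
    df["quadrant"] = [
        classify_quadrant(e3, ie2, library)
        for e3, ie2 in zip(df["logFC(ER3)"], df["invER2"])
    ]
    df["library"] = library
    df = df.sort_values(
        by=["P.Value", "t", "ID"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "t" else col,
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return df[TOP_TABLE_COLUMNS]


def write_top_table(df: pd.DataFrame, path) -> None:
    """Write a top table as a tab-delimited file with the published header."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_er_plot(
    rows: pd.DataFrame,
    path=None,
    top_n: int = 300,
    alpha: float = 0.05,
    group_ids: dict | None = None,
) -> dict:
    """ER3-vs-invER2 scatter with quadrant gridlines; returns summary counts.

    The min(top_n, #{adj.P.Val < alpha}) most significant clones are
    highlighted.  When ``path`` is given, a PNG (or SVG) and the
    underlying tab-delimited table with a ``highlight`` flag are written.
    ``group_ids`` (clone id -> redundant-group id) colour-codes points by
    group, reproducing the clustering view of redundant partners.

    The returned summary reports quadrant counts and the significant /
    positive-B percentages over all classified clones and over the
    highlighted subset.
    """
    df = rows.copy()
    sig = df["adj.P.Val"] < alpha
    n_highlight = min(top_n, int(sig.sum()))
    highlight = np.zeros(len(df), dtype=bool)
    highlight[np.flatnonzero(sig.to_numpy())[:n_highlight]] = True  # rows pre-sorted by p
    df["highlight"] = highlight

    classified = df["quadrant"] != "Unclassified"
    quad_counts = df.loc[classified, "quadrant"].value_counts().to_dict()
    quad_counts_highlight = (
        df.loc[classified & highlight, "quadrant"].value_counts().to_dict()
    )
    n_cls = int(classified.sum())
    summary = {
        "n_clones": int(len(df)),
        "n_classified": n_cls,
        "n_unclassified": int(len(df) - n_cls),
        "n_significant": int(sig.sum()),
        "n_highlighted": n_highlight,
        "pct_significant": 100.0 * sig.mean() if len(df) else np.nan,
        "pct_positive_b": 100.0 * (df["B"] > 0).mean() if len(df) else np.nan,
        "quadrant_counts": quad_counts,
        "quadrant_counts_highlighted": quad_counts_highlight,
        "pct_quadrant1_all": 100.0 * quad_counts.get(_dominant_quadrant(df), 0) / n_cls
        if n_cls
        else np.nan,
    }

    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        path = Path(path)
        fig, ax = plt.subplots(figsize=(6, 6))
        x, y = df["invER2"], df["logFC(ER3)"]
        if group_ids:
            colors = pd.Series([group_ids.get(i, -1) for i in df["ID"]])
            ax.scatter(x, y, c=colors, s=12, cmap="tab20", alpha=0.8)
        else:
            ax.scatter(x[~highlight], y[~highlight], s=6, c="0.7", label="other")
            ax.scatter(
                x[highlight], y[highlight], s=10, c="tab:blue",
                label=f"top {n_highlight} (adj p < {alpha:g})",
            )
            ax.legend(loc="best", fontsize=8)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("inverse ER2 (log2)")
        ax.set_ylabel("ER3 (log2)")
        lib = df["library"].iloc[0] if len(df) else ""
        ax.set_title(f"{lib} library enrichment-ratio plot")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g")

    log.info("ER plot summary: %s", summary)
    return summary


def _dominant_quadrant(df: pd.DataFrame) -> str:
    """Quadrant 1 of the plot: ER3 > 0 and invER2 < 0 in either library."""
    lib = df["library"].iloc[0] if len(df) else "forward"
    return "Up.Rare" if lib == "forward" else "Down.Rare"
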