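"""Synthetic SSH-screening experiments with known ground truth.

Generates a complete file bundle — GPR files, GAL, Targets, SpotTypes,
clone FASTA — plus a truth table, emulating the study design of a
forward+reverse SSH library screen on two-colour arrays:

* duplicate-spotted clone libraries laid out in print-tip blocks, each
  clone printed once on each half of the slide;
* four alien control probes (globin, its, nptII, gfp) spiked at fixed
  mass ratios (45 : 45 : 4.5 : 0.45 ng) and spotted as five two-fold
  dilution series in one row of several blocks — identical true
  abundance in both channels, so their true M is zero;
* three contrasts (UT vs UC, UT vs ST, UC vs SC), each hybridised on
  ``arrays_per_contrast`` arrays with half the arrays dye-swapped;
* spot intensities drawn from the normexp model: an exponential
  spot-deposition amount shared between the two channels, scaled by each
  channel's sample abundance, plus normal background — with a smooth
  cubic dye bias in A multiplying the Cy5 channel;
* a configurable fraction of truly differentially expressed clones and
  of "rare" clones (enriched by the subtraction), and planted redundant
  clone groups that share one underlying transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import classify_quadrant

__all__ = ["SimConfig", "SimBundle", "generate_experiment", "score_against_truth",
           "partition_scores"]

CONTROL_PROBES = ("globin", "its", "nptii", "gfp")


@dataclass
class SimConfig:
    """Study conditions for one synthetic screen.

    Defaults mirror the screening design the generator emulates: ~2000
    clones per library printed in duplicate, 10% truly differentially
    expressed at a mean |log2 ratio| of 2, 88% of clones rare before
    subtraction, per-array log-ratio noise of 0.35 log2 units, and four
    arrays (two dye swaps) per contrast.
    """

    n_forward: int = 2000
    n_reverse: int = 2000
    blocks: int = 16
    rows: int = 24
    cols: int = 22
    control_row: int = 12  # dilution series live in this row of the first blocks
    control_blocks_per_half: int = 4
    de_fraction: float = 0.10
    de_logfc: float = 2.0
    wrong_side_fraction: float = 0.08  # clones that ended up in the wrong library
    rare_fraction: float = 0.88
    noise_sd: float = 0.35  # array x clone log2-ratio noise
    tech_sd: float = 0.07  # per-spot per-channel log2 noise
    dye_bias_amplitude: float = 0.55  # log2 units, smooth cubic in A on Cy5
    control_mix: tuple = (45.0, 45.0, 4.5, 0.45)  # globin, its, nptII, gfp (ng)
    dilution_steps: int = 5  # two-fold series
    arrays_per_contrast: int = 4  # half of them dye-swapped
    redundant_fraction: float = 0.15  # clones in multi-member transcript groups
    n_sequenced: int = 120
    bg_mean: float = 120.0
    bg_sd: float = 22.0
    low_quality_fraction: float = 0.03
    signal_model: str = "exponential"  # "gamma" = misspecified robustness mode
    background: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.de_fraction <= 1 and 0 <= self.rare_fraction <= 1):
            raise ValueError("de_fraction and rare_fraction must be in [0, 1]")
        if self.blocks % 2:
            raise ValueError("blocks must be even (duplicate half-slides)")


@dataclass
class SimBundle:
    """Paths of a generated experiment plus its ground truth."""

    out_dir: Path
    gpr_files: list
    gal_file: Path
    targets_file: Path
    spottypes_file: Path
    fasta_file: Path
    truth_file: Path
    truth: pd.DataFrame
    layout: pd.DataFrame
    arrays: list = field(default_factory=list)  # per-array canonical frames


# ---------------------------------------------------------------------------
# Layout


def _build_layout(cfg: SimConfig) -> pd.DataFrame:
    """Printed-spot layout shared by every array of the experiment."""
    half = cfg.blocks // 2
    ctrl_blocks = set(range(1, cfg.control_blocks_per_half + 1))
    # control combos fill the control row, dilution-major so every probe
    # appears even on narrow grids; two undiluted repeats pad the row
    combos = [(p, k) for k in range(cfg.dilution_steps) for p in CONTROL_PROBES]
    combos += [("globin", 0), ("its", 0)]
    combos = combos[: cfg.cols]

    rows = []
    for block in range(1, half + 1):
        for row in range(1, cfg.rows + 1):
            for col in range(1, cfg.cols + 1):
                if block in ctrl_blocks and row == cfg.control_row and col <= len(combos):
                    probe, dil = combos[col - 1]
                    rows.append((block, row, col, f"{probe}_d{dil + 1}", "control"))
                else:
                    rows.append((block, row, col, "", "library"))
    layout = pd.DataFrame(rows, columns=["block", "row", "col", "clone_id", "kind"])

    free = layout.index[(layout["kind"] == "library")].to_numpy()
    n_clones = cfg.n_forward + cfg.n_reverse
    if n_clones > free.size:
        raise ValueError(
            f"grid too small: {n_clones} clones but only {free.size} library positions per half-slide"
        )
    ids = [f"c{i + 1:04d}-F" for i in range(cfg.n_forward)] + [
        f"c{i + 1:04d}-R" for i in range(cfg.n_reverse)
    ]
    col_ids = layout["clone_id"].to_numpy(object)
    col_ids[free[: len(ids)]] = ids
    blank = free[len(ids):]
    col_ids[blank] = "blank"
    layout["clone_id"] = col_ids
    layout.loc[layout["clone_id"] == "blank", "kind"] = "blank"

    # duplicate half: same positions shifted by `half` blocks
    dup = layout.copy()
    dup["block"] = dup["block"] + half
    return pd.concat([layout, dup], ignore_index=True)


# ---------------------------------------------------------------------------
# Truth


def _simulate_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-clone ground truth; redundant partners share their transcript's values."""
    records = []
    tid = 0
    for lib, n in (("forward", cfg.n_forward), ("reverse", cfg.n_reverse)):
        assigned = 0
        while assigned < n:
            tid += 1
            if rng.random() < cfg.redundant_fraction / 2.5:
                size = int(rng.integers(2, 5))
            else:
                size = 1
            size = min(size, n - assigned)
            base = rng.uniform(6.0, 12.0)
            is_de = rng.random() < cfg.de_fraction
            if is_de:
                mag = max(0.25, rng.normal(cfg.de_logfc, 0.25 * cfg.de_logfc))
                er3 = mag if rng.random() >= cfg.wrong_side_fraction else -mag
            else:
                er3 = 0.0
            if rng.random() < cfg.rare_fraction:
                inv_er2 = -max(0.3, abs(rng.normal(2.0, 0.6)))
            else:
                inv_er2 = max(0.3, abs(rng.normal(1.0, 0.4)))
            for _ in range(size):
                assigned += 1
                prefix = "c" if lib == "forward" else "c"
                num = assigned if lib == "forward" else assigned
                suffix = "F" if lib == "forward" else "R"
                records.append(
                    {
                        "clone_id": f"{prefix}{num:04d}-{suffix}",
                        "library": lib,
                        "transcript_id": f"T{tid:05d}",
                        "is_de": is_de,
                        "true_er3": er3,
                        "true_inv_er2": inv_er2,
                        "base_level": base,
                    }
                )
    truth = pd.DataFrame(records)
    sizes = truth.groupby("transcript_id")["clone_id"].transform("size")
    truth["group_size"] = sizes
    return truth


def _sample_levels(truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """True log2 abundance of each clone in each of the four samples."""
    theta = np.where(
        truth["library"] == "forward", truth["true_er3"], -truth["true_er3"]
    )  # canonical log2(UT/UC)
    base = truth["base_level"].to_numpy()
    mu_ut = base + theta / 2.0
    mu_uc = base - theta / 2.0
    nuis = rng.normal(0.0, 0.5, size=len(truth))
    fwd = (truth["library"] == "forward").to_numpy()
    mu_st = np.where(fwd, mu_ut - truth["true_inv_er2"], mu_ut + nuis)
    mu_sc = np.where(~fwd, mu_uc - truth["true_inv_er2"], mu_uc + nuis)
    return pd.DataFrame(
        {"UT": mu_ut, "UC": mu_uc, "ST": mu_st, "SC": mu_sc}, index=truth["clone_id"]
    )


# ---------------------------------------------------------------------------
# Array simulation


def _dye_bias(a_true: np.ndarray, amplitude: float) -> np.ndarray:
    z = np.clip((a_true - 9.0) / 4.0, -1.0, 1.0)
    return amplitude * (z**3 - 0.5 * z + 0.25)


def _control_levels(cfg: SimConfig) -> dict[str, float]:
    out = {}
    for probe, mass in zip(CONTROL_PROBES, cfg.control_mix):
        for k in range(cfg.dilution_steps):
            out[f"{probe}_d{k + 1}"] = 10.0 + np.log2(mass) - k
    return out


def _simulate_array(
    cfg: SimConfig,
    layout: pd.DataFrame,
    levels: pd.DataFrame,
    cy3: str,
    cy5: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(layout)
    ctrl_levels = _control_levels(cfg)
    lib_mask = (layout["kind"] == "library").to_numpy()
    ctrl_mask = (layout["kind"] == "control").to_numpy()
    ids = layout["clone_id"].to_numpy(object)

    lvl5 = np.full(n, -np.inf)
    lvl3 = np.full(n, -np.inf)
    lib_ids = ids[lib_mask]
    lvl5[lib_mask] = levels.loc[lib_ids, cy5].to_numpy()
    lvl3[lib_mask] = levels.loc[lib_ids, cy3].to_numpy()
    clevels = np.array([ctrl_levels[i] for i in ids[ctrl_mask]])
    lvl5[ctrl_mask] = clevels
    lvl3[ctrl_mask] = clevels

    # array x clone interaction noise on the log-ratio, shared by duplicates
    uniq = pd.unique(lib_ids)
    eta_by_clone = pd.Series(rng.normal(0.0, cfg.noise_sd, size=len(uniq)), index=uniq)
    eta = np.zeros(n)
    eta[lib_mask] = eta_by_clone.loc[lib_ids].to_numpy()
    lvl5 = lvl5 + eta / 2.0
    lvl3 = lvl3 - eta / 2.0
    if cfg.tech_sd > 0:
        lvl5 = lvl5 + rng.normal(0.0, cfg.tech_sd, size=n)
        lvl3 = lvl3 + rng.normal(0.0, cfg.tech_sd, size=n)

    a_true = (lvl5 + lvl3) / 2.0
    bias = _dye_bias(np.where(np.isfinite(a_true), a_true, 9.0), cfg.dye_bias_amplitude)

    if cfg.noise_sd == 0 and cfg.tech_sd == 0:
        # noiseless regime: spot deposition is deterministic too
        amount = np.ones(n)
    elif cfg.signal_model == "gamma":
        amount = rng.gamma(2.0, 0.5, size=n)
    else:
        amount = rng.exponential(1.0, size=n)
    sig5 = np.where(np.isfinite(lvl5), amount * np.exp2(lvl5 + bias), 0.0)
    sig3 = np.where(np.isfinite(lvl3), amount * np.exp2(lvl3), 0.0)

    flags = np.zeros(n, dtype=int)
    if cfg.low_quality_fraction > 0:
        bad = rng.random(n) < cfg.low_quality_fraction
        idx = np.flatnonzero(bad)
        half = idx[: idx.size // 2]
        rest = idx[idx.size // 2:]
        flags[half] = -50
        sig5[rest] = 0.0
        sig3[rest] = 0.0

    if cfg.background:
        bg5 = rng.normal(cfg.bg_mean, cfg.bg_mean * 0.1, size=n)
        bg3 = rng.normal(cfg.bg_mean, cfg.bg_mean * 0.1, size=n)
        bg_sd5 = rng.uniform(0.8 * cfg.bg_sd, 1.2 * cfg.bg_sd, size=n)
        bg_sd3 = rng.uniform(0.8 * cfg.bg_sd, 1.2 * cfg.bg_sd, size=n)
        # the background SD column is the pixelwise SD; spot medians carry
        # noise on the same scale
        fg5 = sig5 + bg5 + rng.normal(0.0, bg_sd5)
        fg3 = sig3 + bg3 + rng.normal(0.0, bg_sd3)
    else:
        bg5 = bg3 = np.zeros(n)
        bg_sd5 = bg_sd3 = np.full(n, 1e-3)
        fg5, fg3 = sig5, sig3

    fg5 = np.clip(np.round(fg5, 6), 0, None)
    fg3 = np.clip(np.round(fg3, 6), 0, None)
    bg5 = np.clip(np.round(bg5, 6), 0, None)
    bg3 = np.clip(np.round(bg3, 6), 0, None)
    bg_sd5 = np.round(bg_sd5, 6)
    bg_sd3 = np.round(bg_sd3, 6)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr5 = np.round((fg5 - bg5) / bg_sd5, 6)
        snr3 = np.round((fg3 - bg3) / bg_sd3, 6)

    return pd.DataFrame(
        {
            "Block": layout["block"].to_numpy(),
            "Column": layout["col"].to_numpy(),
            "Row": layout["row"].to_numpy(),
            "ID": ids,
            "Name": ids,
            "F635 Median": fg5,
            "B635 Median": bg5,
            "F532 Median": fg3,
            "B532 Median": bg3,
            "B635 SD": bg_sd5,
            "B532 SD": bg_sd3,
            "SNR 635": snr5,
            "SNR 532": snr3,
            "Flags": flags,
        }
    )


def _write_atf(path: Path, df: pd.DataFrame, header: list[str]) -> None:
    with open(path, "w", encoding="latin-1") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(header)}\t{len(df.columns)}\n")
        for h in header:
            fh.write(f'"{h}"\n')
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Clone FASTA with planted redundancy


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _make_fasta(
    cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator, path: Path
) -> pd.DataFrame:
    """FASTA for a sequenced subset, preferring multi-member groups.

    Each transcript gets one random reference sequence; its clones carry
    overlapping fragments (some reverse-complemented) flanked by vector
    arm and SSH adaptor sequences from the bundled database.
    """
    from .seqgroup import default_vector_db

    vec = dict(default_vector_db())
    arm_l, arm_r = vec["vector_arm_left"], vec["vector_arm_right"]
    ad1, ad2 = vec["ssh_adaptor_1"], vec["ssh_adaptor_2r"]

    by_group = truth.sort_values("clone_id").groupby("transcript_id", sort=True)
    ordered = sorted(
        by_group.groups, key=lambda t: (-len(by_group.get_group(t)), t)
    )
    chosen: list[tuple[str, str]] = []
    tseqs: dict[str, str] = {}
    picked_rows = []
    for t in ordered:
        grp = by_group.get_group(t)
        if len(chosen) + len(grp) > cfg.n_sequenced and len(grp) > 1:
            continue
        if len(chosen) >= cfg.n_sequenced:
            break
        tlen = int(rng.integers(450, 700))
        tseqs[t] = _random_seq(rng, tlen)
        anchor = int(rng.integers(0, max(1, tlen - 250)))
        for _, row in grp.iterrows():
            if len(chosen) >= cfg.n_sequenced:
                break
            flen = int(rng.integers(180, 320))
            lo = max(0, anchor - 40)
            start = int(rng.integers(lo, min(max(lo + 1, tlen - flen), anchor + 41)))
            frag = tseqs[t][start : start + flen]
            if rng.random() < 0.3:
                frag = _revcomp(frag)
            seq = arm_l[-int(rng.integers(20, 60)):] + ad1 + frag + ad2 + arm_r[: int(rng.integers(20, 60))]
            chosen.append((row["clone_id"], seq))
            picked_rows.append(row)
    with open(path, "w") as fh:
        for cid, seq in sorted(chosen):
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return pd.DataFrame(picked_rows)


# ---------------------------------------------------------------------------
# Top-level generation


def generate_experiment(cfg: SimConfig, out_dir) -> SimBundle:
    """Write a full synthetic screening bundle; deterministic given cfg.seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    layout = _build_layout(cfg)
    truth = _simulate_truth(cfg, rng)
    levels = _sample_levels(truth, rng)

    # targets: three contrasts, half of each contrast's arrays dye-swapped
    contrast_pairs = [("er3", "UT", "UC"), ("er2f", "UT", "ST"), ("er2r", "UC", "SC")]
    target_rows = []
    for cname, num, den in contrast_pairs:
        for k in range(cfg.arrays_per_contrast):
            swapped = k % 2 == 1
            cy5, cy3 = (den, num) if swapped else (num, den)
            aid = f"{cname}_{k + 1}"
            target_rows.append(
                {"ArrayID": aid, "FileName": f"{aid}.gpr", "Cy3": cy3, "Cy5": cy5}
            )
    targets = pd.DataFrame(target_rows)

    gpr_files = []
    arrays = []
    wavelength_header = ["Wavelengths=635\t532", "Type=GenePix Results 3"]
    for _, trow in targets.iterrows():
        df = _simulate_array(cfg, layout, levels, trow["Cy3"], trow["Cy5"], rng)
        p = out_dir / trow["FileName"]
        _write_atf(p, df, wavelength_header)
        gpr_files.append(p)
        arrays.append(df)

    gal = layout.rename(
        columns={"block": "Block", "col": "Column", "row": "Row", "clone_id": "ID"}
    )[["Block", "Column", "Row", "ID"]].copy()
    gal["Name"] = gal["ID"]
    gal_file = out_dir / "layout.gal"
    _write_atf(gal_file, gal, ["Type=GenePix ArrayList V1.0"])

    targets_file = out_dir / "targets.tsv"
    targets.to_csv(targets_file, sep="\t", index=False)

    spottypes = pd.DataFrame(
        [
            ("control_globin", "globin*", "*"),
            ("control_its", "its*", "*"),
            ("control_nptii", "nptii*", "*"),
            ("control_gfp", "gfp*", "*"),
            ("forward_library", "*-F", "*"),
            ("reverse_library", "*-R", "*"),
            ("blank", "*", "*"),
        ],
        columns=["SpotType", "ID", "Name"],
    )
    spottypes_file = out_dir / "spottypes.tsv"
    spottypes.to_csv(spottypes_file, sep="\t", index=False)

    fasta_file = out_dir / "clones.fasta"
    sequenced = _make_fasta(cfg, truth, rng, fasta_file)
    truth = truth.copy()
    truth["sequenced"] = truth["clone_id"].isin(sequenced["clone_id"])

    truth_file = out_dir / "truth.tsv"
    truth.to_csv(truth_file, sep="\t", index=False)

    return SimBundle(
        out_dir=out_dir,
        gpr_files=gpr_files,
        gal_file=gal_file,
        targets_file=targets_file,
        spottypes_file=spottypes_file,
        fasta_file=fasta_file,
        truth_file=truth_file,
        truth=truth,
        layout=layout,
        arrays=arrays,
    )


# ---------------------------------------------------------------------------
# Scoring


def score_against_truth(
    top_tables: dict[str, pd.DataFrame], truth: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Pipeline metrics against the planted truth.

    Power and empirical FDR are computed among clones with a usable
    estimate (finite adjusted p); the FDR denominator is the set of
    adj_p < alpha calls.  Sign accuracy is restricted to detected truly
    DE clones; quadrant accuracy compares the predicted label with the
    one implied by the true enrichment ratios.
    """
    frames = [t for t in top_tables.values() if t is not None and len(t)]
    est = pd.concat(frames, ignore_index=True)
    merged = est.merge(truth, left_on="ID", right_on="clone_id", how="inner")
    if len(merged) == 0:
        raise ValueError("no clone ids shared between top tables and truth")
    usable = merged["adj.P.Val"].notna()
    m = merged[usable]
    called = m["adj.P.Val"] < alpha
    de = m["is_de"].astype(bool)
    power = float((called & de).sum() / de.sum()) if de.sum() else np.nan
    fdr = float((called & ~de).sum() / called.sum()) if called.sum() else 0.0
    detected_de = m[called & de]
    sign_acc = (
        float((np.sign(detected_de["logFC(ER3)"]) == np.sign(detected_de["true_er3"])).mean())
        if len(detected_de)
        else np.nan
    )
    rmse = float(np.sqrt(np.mean((m["logFC(ER3)"] - m["true_er3"]) ** 2)))
    # quadrant accuracy only makes sense where the true ER3 is off zero:
    # non-DE clones sit on the Up/Down boundary and classify by noise
    libcol = m["library_y"] if "library_y" in m else m["library"]
    truth_quad = np.asarray(
        [
            classify_quadrant(e3, ie2, lb)
            for e3, ie2, lb in zip(m["true_er3"], m["true_inv_er2"], libcol)
        ]
    )
    on_de = (called & de).to_numpy()
    quad_acc = (
        float((m["quadrant"].to_numpy()[on_de] == truth_quad[on_de]).mean())
        if on_de.any()
        else np.nan
    )
    return {
        "n_scored": int(len(m)),
        "power": power,
        "empirical_fdr": fdr,
        "sign_accuracy": sign_acc,
        "er3_rmse": rmse,
        "quadrant_accuracy": quad_acc,
        "frac_called": float(called.mean()),
    }


def partition_scores(predicted: list, truth: pd.DataFrame) -> dict:
    """Pair-level precision/recall of redundant-group recovery.

    ``predicted`` is a list of RedundantGroup; truth pairs are clones
    sharing a transcript_id.
    """
    def pairs_of(groups):
        out = set()
        for members in groups:
            ms = sorted(members)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    out.add((ms[i], ms[j]))
        return out

    pred_pairs = pairs_of([g.member_ids for g in predicted])
    known = {m for g in predicted for m in g.member_ids}
    tsub = truth[truth["clone_id"].isin(known)]
    true_pairs = pairs_of(
        [grp["clone_id"].tolist() for _, grp in tsub.groupby("transcript_id")]
    )
    tp = len(pred_pairs & true_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return {"precision": precision, "recall": recall,
            "n_pred_pairs": len(pred_pairs), "n_true_pairs": len(true_pairs)}
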