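"""Readers for the four standard input files of a two-colour SSH screen.

GenePix Results (GPR) files carry per-spot fluorescence quantification in
the Axon Text File (ATF) dialect; the GenePix Array List (GAL) declares the
printed layout; a Targets table maps each array to the Cy3/Cy5 samples it
hybridised; a SpotTypes table maps clone-id patterns onto spot roles
(library probe, spike-in control, blank).

All files are tab-delimited and read as Latin-1, since GPR files in the
wild are not UTF-8 clean.  Grid addresses stay 1-based as printed; the
internal spot index is 0-based in file order.
"""

from __future__ import annotations

import fnmatch
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ArraySpots",
    "GalLayout",
    "SpotTypeRule",
    "ExperimentDesign",
    "ArrayFileError",
    "DesignError",
    "read_gpr",
    "read_gal",
    "read_design",
    "SAMPLES",
    "CONTRASTS",
]


class ArrayFileError(ValueError):
    """Raised when a GPR/GAL/Targets/SpotTypes file cannot be parsed."""


class DesignError(ValueError):
    """Raised when the experiment design is internally inconsistent."""


#: The four cDNA samples of a forward+reverse SSH screen: unsubtracted
#: treated/control and subtracted treated/control.
SAMPLES = ("UT", "UC", "ST", "SC")

#: Contrast name -> (sample pair, numerator sample).  The numerator fixes
#: the dye orientation sign: +1 when the numerator was labelled with Cy5.
CONTRASTS = {
    "er3": (frozenset({"UT", "UC"}), "UT"),
    "er2_forward": (frozenset({"UT", "ST"}), "UT"),
    "er2_reverse": (frozenset({"UC", "SC"}), "UC"),
}

ROLES = (
    "forward_library",
    "reverse_library",
    "control_gfp",
    "control_globin",
    "control_nptii",
    "control_its",
    "blank",
)

_ROLE_ALIASES = {
    "forward": "forward_library",
    "forward_library": "forward_library",
    "cdna_f": "forward_library",
    "reverse": "reverse_library",
    "reverse_library": "reverse_library",
    "cdna_r": "reverse_library",
    "gfp": "control_gfp",
    "control_gfp": "control_gfp",
    "globin": "control_globin",
    "control_globin": "control_globin",
    "nptii": "control_nptii",
    "control_nptii": "control_nptii",
    "its": "control_its",
    "control_its": "control_its",
    "blank": "blank",
    "empty": "blank",
}

#: Scanner wavelength labels that mean the red (Cy5) and green (Cy3) channel.
CY5_WAVELENGTHS = ("635", "633", "647", "670")
CY3_WAVELENGTHS = ("532", "543", "555", "570")

_CANONICAL = [
    "block",
    "row",
    "col",
    "clone_id",
    "name",
    "fg_cy5",
    "bg_cy5",
    "fg_cy3",
    "bg_cy3",
    "bg_sd_cy5",
    "bg_sd_cy3",
    "snr_cy5",
    "snr_cy3",
    "flag",
]


@dataclass
class ArraySpots:
    """All spot-level measurements and metadata for one scanned array.

    ``spots`` holds one row per printed spot, in file order, with the
    canonical columns block/row/col (1-based), clone_id, foreground and
    background medians and background SDs per channel, per-channel
    signal-to-noise ratios and the GenePix flag (negative = bad spot).
    Columns the reader did not recognise are preserved in ``extra``.
    """

    array_id: str
    spots: pd.DataFrame
    channel_names: tuple[str, str]  # (cy3 wavelength label, cy5 wavelength label)
    extra: pd.DataFrame | None = None
    header: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class GalLayout:
    """Printed-grid declaration from a GenePix Array List."""

    spots: pd.DataFrame  # block, row, col, clone_id, name in print order
    blocks: int
    rows: int
    cols: int

    @property
    def n_spots(self) -> int:
        return self.blocks * self.rows * self.cols


@dataclass
class SpotTypeRule:
    role: str
    id_pattern: str
    name_pattern: str = "*"

    def matches(self, clone_id: str, name: str = "") -> bool:
        return fnmatch.fnmatchcase(clone_id, self.id_pattern) and fnmatch.fnmatchcase(
            name, self.name_pattern
        )


@dataclass
class ExperimentDesign:
    """Array-to-sample mapping plus spot-role rules for one experiment.

    ``targets`` has one row per array with columns array_id, filename,
    cy3, cy5 (sample labels), contrast and orientation (+1 when the
    contrast's numerator sample was Cy5-labelled, -1 for the dye swap).
    """

    targets: pd.DataFrame
    spot_types: list[SpotTypeRule]
    layout: GalLayout | None = None
    library_mode: str = "both"

    def arrays_for(self, contrast: str) -> pd.DataFrame:
        return self.targets[self.targets["contrast"] == contrast]

    def assign_roles(self, clone_ids, names=None) -> np.ndarray:
        """Map clone ids to spot roles; first matching rule wins."""
        if names is None:
            names = [""] * len(clone_ids)
        out = np.empty(len(clone_ids), dtype=object)
        for i, (cid, nm) in enumerate(zip(clone_ids, names)):
            role = "blank"
            for rule in self.spot_types:
                if rule.matches(str(cid), str(nm)):
                    role = rule.role
                    break
            out[i] = role
        return out


# ---------------------------------------------------------------------------
# ATF parsing


def _read_atf(path) -> tuple[dict, pd.DataFrame]:
    """Parse an Axon Text File into (header dict, data frame)."""
    text = Path(path).read_text(encoding="latin-1")
    lines = text.splitlines()
    if not lines or not text.strip():
        raise ArrayFileError(f"empty file: {path}")
    header: dict[str, str] = {}
    start = 0
    if lines[0].upper().startswith("ATF"):
        try:
            n_head = int(lines[1].split("\t")[0])
        except (IndexError, ValueError) as exc:
            raise ArrayFileError(f"malformed ATF counts line in {path}") from exc
        for raw in lines[2 : 2 + n_head]:
            entry = raw.strip().strip('"')
            if "=" in entry:
                key, val = entry.split("=", 1)
                header[key.strip()] = val.strip()
        start = 2 + n_head
    else:
        # headerless dialect: scan for the column-name row
        for i, raw in enumerate(lines):
            fields = [f.strip().strip('"') for f in raw.split("\t")]
            if "Block" in fields and ("ID" in fields or "Row" in fields):
                start = i
                break
        else:
            raise ArrayFileError(f"no column-name row found in {path}")
    body = "\n".join(lines[start:])
    if not body.strip():
        raise ArrayFileError(f"no data rows in {path}")
    df = pd.read_csv(io.StringIO(body), sep="\t", quotechar='"', dtype=str)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    return header, df


def _channel_column(columns, template: str, wavelengths) -> tuple[str, str] | None:
    for w in wavelengths:
        name = template.format(w=w)
        if name in columns:
            return name, w
    return None


def _to_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ArrayFileError(
            f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row + 1} of {path}"
        )
    return vals.to_numpy(dtype=float)


def read_gpr(path, layout: GalLayout | None = None, array_id: str | None = None) -> ArraySpots:
    """Read a GenePix Results file into an :class:`ArraySpots`.

    Parameters
    ----------
    path
        Tab-delimited GPR file (ATF dialect).
    layout
        Optional expected grid; a mismatch in spot count or block/row/col
        extents raises :class:`ArrayFileError`.
    array_id
        Identifier for the array; defaults to the file stem.

    Per-channel signal-to-noise ratios are taken from the file's own
    ``SNR`` columns when present, otherwise computed as
    (foreground median - background median) / background SD.
    """
    header, df = _read_atf(path)
    cols = set(df.columns)

    for required in ("Block", "Row", "Column", "ID"):
        if required not in cols:
            raise ArrayFileError(f"missing required column {required!r} in {path}")

    fg5 = _channel_column(cols, "F{w} Median", CY5_WAVELENGTHS)
    bg5 = _channel_column(cols, "B{w} Median", CY5_WAVELENGTHS)
    fg3 = _channel_column(cols, "F{w} Median", CY3_WAVELENGTHS)
    bg3 = _channel_column(cols, "B{w} Median", CY3_WAVELENGTHS)
    for need, label in ((fg5, "F<cy5> Median"), (bg5, "B<cy5> Median"),
                        (fg3, "F<cy3> Median"), (bg3, "B<cy3> Median")):
        if need is None:
            raise ArrayFileError(f"missing required column {label!r} in {path}")
    w5, w3 = fg5[1], fg3[1]

    sd5 = _channel_column(cols, "B{w} SD", (w5,))
    sd3 = _channel_column(cols, "B{w} SD", (w3,))
    snr5 = _channel_column(cols, "SNR {w}", (w5,))
    snr3 = _channel_column(cols, "SNR {w}", (w3,))
    if sd5 is None and snr5 is None:
        raise ArrayFileError(f"neither 'B{w5} SD' nor 'SNR {w5}' present in {path}")
    if sd3 is None and snr3 is None:
        raise ArrayFileError(f"neither 'B{w3} SD' nor 'SNR {w3}' present in {path}")
    if "Flags" not in cols:
        raise ArrayFileError(f"missing required column 'Flags' in {path}")

    out = pd.DataFrame(
        {
            "block": _to_numeric(df, "Block", path).astype(int),
            "row": _to_numeric(df, "Row", path).astype(int),
            "col": _to_numeric(df, "Column", path).astype(int),
            "clone_id": df["ID"].astype(str).str.strip(),
            "name": df["Name"].astype(str).str.strip() if "Name" in cols else "",
            "fg_cy5": _to_numeric(df, fg5[0], path),
            "bg_cy5": _to_numeric(df, bg5[0], path),
            "fg_cy3": _to_numeric(df, fg3[0], path),
            "bg_cy3": _to_numeric(df, bg3[0], path),
            "flag": _to_numeric(df, "Flags", path).astype(int),
        }
    )
    out["bg_sd_cy5"] = _to_numeric(df, sd5[0], path) if sd5 else np.nan
    out["bg_sd_cy3"] = _to_numeric(df, sd3[0], path) if sd3 else np.nan
    if snr5:
        out["snr_cy5"] = _to_numeric(df, snr5[0], path)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["snr_cy5"] = (out["fg_cy5"] - out["bg_cy5"]) / out["bg_sd_cy5"]
    if snr3:
        out["snr_cy3"] = _to_numeric(df, snr3[0], path)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["snr_cy3"] = (out["fg_cy3"] - out["bg_cy3"]) / out["bg_sd_cy3"]

    for c in ("fg_cy5", "bg_cy5", "fg_cy3", "bg_cy3"):
        vals = out[c].to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ArrayFileError(f"column {c} contains negative or non-finite medians in {path}")

    known = {
        "Block", "Row", "Column", "ID", "Name", "Flags",
        fg5[0], bg5[0], fg3[0], bg3[0],
    }
    for opt in (sd5, sd3, snr5, snr3):
        if opt:
            known.add(opt[0])
    extra = df[[c for c in df.columns if c not in known]].copy()

    if layout is not None:
        if len(out) != layout.n_spots:
            raise ArrayFileError(
                f"{path}: {len(out)} spots but layout declares {layout.n_spots}"
            )
        if (
            out["block"].max() != layout.blocks
            or out["row"].max() != layout.rows
            or out["col"].max() != layout.cols
        ):
            raise ArrayFileError(f"{path}: grid extents disagree with the GAL layout")

    aid = array_id if array_id is not None else Path(path).stem
    return ArraySpots(
        array_id=aid,
        spots=out,
        channel_names=(w3, w5),
        extra=extra if len(extra.columns) else None,
        header=header,
    )


def read_gal(path) -> GalLayout:
    """Read a GenePix Array List into a :class:`GalLayout`."""
    _, df = _read_atf(path)
    for required in ("Block", "Row", "Column", "ID"):
        if required not in df.columns:
            raise ArrayFileError(f"missing required column {required!r} in {path}")
    spots = pd.DataFrame(
        {
            "block": _to_numeric(df, "Block", path).astype(int),
            "row": _to_numeric(df, "Row", path).astype(int),
            "col": _to_numeric(df, "Column", path).astype(int),
            "clone_id": df["ID"].astype(str).str.strip(),
            "name": df["Name"].astype(str).str.strip() if "Name" in df.columns else "",
        }
    )
    return GalLayout(
        spots=spots,
        blocks=int(spots["block"].max()),
        rows=int(spots["row"].max()),
        cols=int(spots["col"].max()),
    )


# ---------------------------------------------------------------------------
# Targets and SpotTypes


def _pick(df: pd.DataFrame, *names: str) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for n in names:
        if n.lower() in lower:
            return lower[n.lower()]
    return None


def _normalize_sample(label: str) -> str:
    s = str(label).strip().upper()
    if s not in SAMPLES:
        raise DesignError(
            f"sample label {label!r} not in the UT/UC/ST/SC vocabulary"
        )
    return s


def read_design(
    targets_path,
    spottypes_path,
    gal_path=None,
    library_mode: str = "both",
) -> ExperimentDesign:
    """Read Targets + SpotTypes (+ optional GAL) into an ExperimentDesign.

    Each array is assigned to exactly one contrast from its (Cy3, Cy5)
    sample pair and given a dye orientation: +1 when the contrast's
    numerator sample (UT for ER3 and forward ER2; UC for reverse ER2) was
    in the Cy5 channel, -1 for its dye swap.
    """
    tdf = pd.read_csv(targets_path, sep="\t", comment="#", encoding="latin-1")
    fn_col = _pick(tdf, "FileName", "File", "gpr")
    cy3_col = _pick(tdf, "Cy3")
    cy5_col = _pick(tdf, "Cy5")
    if fn_col is None or cy3_col is None or cy5_col is None:
        raise ArrayFileError(
            f"Targets file {targets_path} needs FileName, Cy3 and Cy5 columns"
        )
    id_col = _pick(tdf, "ArrayID", "SlideNumber", "Name", "Slide")

    rows = []
    for _, rec in tdf.iterrows():
        cy3 = _normalize_sample(rec[cy3_col])
        cy5 = _normalize_sample(rec[cy5_col])
        pair = frozenset({cy3, cy5})
        for cname, (cpair, numerator) in CONTRASTS.items():
            if pair == cpair:
                contrast = cname
                orientation = 1 if cy5 == numerator else -1
                break
        else:
            raise DesignError(
                f"array sample pair ({cy3}, {cy5}) matches no contrast"
            )
        aid = str(rec[id_col]) if id_col else Path(str(rec[fn_col])).stem
        rows.append(
            {
                "array_id": aid,
                "filename": str(rec[fn_col]),
                "cy3": cy3,
                "cy5": cy5,
                "contrast": contrast,
                "orientation": orientation,
            }
        )
    targets = pd.DataFrame(rows)
    if targets["array_id"].duplicated().any():
        dup = targets.loc[targets["array_id"].duplicated(), "array_id"].iloc[0]
        raise DesignError(f"duplicate array_id {dup!r} in Targets")
    for cname, grp in targets.groupby("contrast"):
        if len(grp) < 2:
            raise DesignError(f"contrast {cname} has fewer than 2 arrays")
        if grp["orientation"].nunique() < 2:
            raise DesignError(f"contrast {cname} has no dye swap")

    sdf = pd.read_csv(spottypes_path, sep="\t", comment="#", encoding="latin-1")
    type_col = _pick(sdf, "SpotType")
    idp_col = _pick(sdf, "ID")
    nmp_col = _pick(sdf, "Name")
    if type_col is None or idp_col is None:
        raise ArrayFileError(
            f"SpotTypes file {spottypes_path} needs SpotType and ID columns"
        )
    rules = []
    for _, rec in sdf.iterrows():
        raw = re.sub(r"[^a-z0-9]+", "_", str(rec[type_col]).strip().lower())
        role = _ROLE_ALIASES.get(raw)
        if role is None:
            raise DesignError(f"unknown spot type {rec[type_col]!r}")
        idp = str(rec[idp_col]).strip() or "*"
        nmp = str(rec[nmp_col]).strip() if nmp_col and pd.notna(rec[nmp_col]) else "*"
        rules.append(SpotTypeRule(role=role, id_pattern=idp, name_pattern=nmp or "*"))

    layout = read_gal(gal_path) if gal_path is not None else None
    if library_mode not in ("forward", "reverse", "both"):
        raise DesignError(f"library_mode must be forward/reverse/both, got {library_mode!r}")
    return ExperimentDesign(
        targets=targets, spot_types=rules, layout=layout, library_mode=library_mode
    )
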