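"""Clone-sequence management: trimming, redundancy grouping, exports.

Sequenced library clones arrive as FASTA reads that still carry cloning
vector and SSH adaptor fragments.  This module trims those off by local
alignment against a vector/adaptor database, then groups clones that
carry (fragments of) the same transcript into *redundant partner
groups*: pairwise local alignment over both strands, a Karlin-Altschul
E-value E = K*m*n*exp(-lambda*S), and single-linkage closure of the
relation E < cutoff (default 1e-10).  The longest member of each group
is its representative.  Exports join groups to the screening top tables
and to imported annotation files.

Alignment uses Biopython's PairwiseAligner (exact affine-gap local
alignment) with an 11-mer shared-word pre-filter to skip hopeless pairs;
the default Karlin-Altschul constants (lambda = 1.28, K = 0.46)
approximate ungapped nucleotide-BLAST statistics for +1/-2 scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "SeqRecordSSH",
    "RedundantGroup",
    "AlignmentParams",
    "load_fasta",
    "default_vector_db",
    "trim_vector",
    "pairwise_evalue",
    "group_redundant",
    "read_annotations",
    "merge_annotations_export",
]

log = logging.getLogger(__name__)


@dataclass
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lam: float = 1.28  # nats per score unit
    K: float = 0.46
    evalue_cutoff: float = 1e-10
    min_length: int = 30
    kmer: int = 11
    vector_min_score: float = 16.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.K < 1:
            raise ValueError("K must be in (0, 1)")


@dataclass
class SeqRecordSSH:
    """One clone sequence with its retained-insert interval.

    ``trimmed_range`` is a 0-based half-open interval on the input
    sequence; human-readable reports print it 1-based inclusive.
    """

    clone_id: str
    sequence: str
    trimmed_range: tuple[int, int] | None = None
    source_library: str = "forward"
    rejected: bool = False
    reject_reason: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.sequence and set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"{self.clone_id}: non-nucleotide characters {bad}")

    @property
    def insert(self) -> str:
        if self.trimmed_range is None:
            return self.sequence
        s, e = self.trimmed_range
        return self.sequence[s:e]


@dataclass
class RedundantGroup:
    """Clones judged to carry the same gene fragment."""

    group_id: str
    members: list[SeqRecordSSH] = field(default_factory=list)
    representative: str = ""
    priority_annotation: str = "none"
    annotation_source: str = "none"

    @property
    def member_ids(self) -> list[str]:
        return [m.clone_id for m in self.members]


def load_fasta(path, source_library: str | None = None) -> list[SeqRecordSSH]:
    """Read clone sequences; library inferred from a -F/-R id suffix."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        lib = source_library
        if lib is None:
            lib = "reverse" if rec.id.upper().endswith("-R") else "forward"
        out.append(SeqRecordSSH(clone_id=rec.id, sequence=str(rec.seq), source_library=lib))
    return out


def default_vector_db() -> list[tuple[str, str]]:
    """Bundled vector/adaptor database as (name, sequence) pairs.

    Contains the nested PCR-Select SSH adaptor/primer sequences plus
    synthetic stand-ins for the T/A-cloning vector arms (see the file's
    own header; the arms are generated, not copied from any vendor
    sequence, and are labelled synthetic).
    """
    ref = resources.files("subscreen.data").joinpath("vector_db.synthetic.fasta")
    with resources.as_file(ref) as p:
        return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(p), "fasta")]


# ---------------------------------------------------------------------------
# Alignment


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def pairwise_evalue(
    a: SeqRecordSSH, b: SeqRecordSSH, params: AlignmentParams | None = None
) -> tuple[float, float]:
    """Best local-alignment score over both strands and its E-value.

    E = K * m * n * exp(-lambda * S) with m, n the trimmed lengths;
    symmetric in the two sequences.  Pairs sharing no k-mer on either
    strand are not aligned (score 0, E = K*m*n).
    """
    if params is None:
        params = AlignmentParams()
    sa, sb = a.insert, b.insert
    if len(sa) < params.min_length or len(sb) < params.min_length:
        raise ValueError(
            f"sequences shorter than min_length={params.min_length}: "
            f"{a.clone_id} ({len(sa)}), {b.clone_id} ({len(sb)})"
        )
    score = 0.0
    rb = _revcomp(sb)
    if _shares_kmer(sa, sb, params.kmer) or _shares_kmer(sa, rb, params.kmer):
        aligner = _make_aligner(params)
        score = max(aligner.score(sa, sb), aligner.score(sa, rb))
    evalue = params.K * len(sa) * len(sb) * np.exp(-params.lam * score)
    return float(score), float(evalue)


# ---------------------------------------------------------------------------
# Vector/adaptor trimming


def _vector_hits(seq: str, vector_db, params: AlignmentParams) -> list[tuple[int, int]]:
    """Query intervals (0-based half-open) of vector hits with score >= threshold."""
    aligner = _make_aligner(params)
    hits = []
    for _, vseq in vector_db:
        for v in (vseq, _revcomp(vseq)):
            if len(v) >= params.kmer and not _shares_kmer(seq, v, min(params.kmer, len(v))):
                continue
            try:
                alns = aligner.align(seq, v)
            except (ValueError, OverflowError):
                continue
            if len(alns) == 0 or alns.score < params.vector_min_score:
                continue
            aln = alns[0]
            qstart = int(aln.aligned[0][0][0])
            qend = int(aln.aligned[0][-1][1])
            hits.append((qstart, qend))
    return _merge_intervals(hits)


def _merge_intervals(ivs: list[tuple[int, int]], slack: int = 5) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + slack:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def trim_vector(
    rec: SeqRecordSSH,
    vector_db: list[tuple[str, str]] | None = None,
    params: AlignmentParams | None = None,
    min_length: int | None = None,
) -> SeqRecordSSH:
    """Trim terminal vector/adaptor runs off a clone sequence.

    Local alignments of the sequence against every vector-database entry
    (both strands, score >= ``params.vector_min_score``) are merged into
    intervals; maximal terminal runs are removed iteratively from each
    end.  A hit strictly internal to the remaining insert rejects the
    record as chimeric; an insert shorter than ``min_length`` (default
    30 nt) after trimming rejects it as too short.  Idempotent: trimming
    a trimmed record changes nothing.
    """
    if params is None:
        params = AlignmentParams()
    if min_length is None:
        min_length = params.min_length
    if not rec.sequence:
        raise ValueError(f"{rec.clone_id}: empty sequence")
    if vector_db is None:
        vector_db = default_vector_db()

    start, end = rec.trimmed_range if rec.trimmed_range else (0, len(rec.sequence))
    slack = 5
    for _ in range(20):  # ends trimmed alternately until stable
        insert = rec.sequence[start:end]
        if end - start < min_length:
            return replace(
                rec, trimmed_range=(start, end), rejected=True, reject_reason="too_short"
            )
        hits = _vector_hits(insert, vector_db, params)
        if not hits:
            break
        moved = False
        for s, e in hits:
            if s <= slack:  # terminal run at the 5' end
                start += e
                moved = True
                break
            if e >= len(insert) - slack:  # terminal run at the 3' end
                end = start + s
                moved = True
                break
        if not moved:
            return replace(
                rec, trimmed_range=(start, end), rejected=True, reject_reason="chimeric"
            )
    if end - start < min_length:
        return replace(
            rec, trimmed_range=(start, end), rejected=True, reject_reason="too_short"
        )
    return replace(rec, trimmed_range=(start, end), rejected=False, reject_reason="")


# ---------------------------------------------------------------------------
# Redundant-partner grouping


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_redundant(
    seqs: list[SeqRecordSSH], params: AlignmentParams | None = None
) -> list[RedundantGroup]:
    """Partition accepted sequences into redundant partner groups.

    Two clones are partners when their pairwise E-value is below the
    cutoff; groups are the connected components of that relation
    (single-linkage closure), which is the only partition stable under
    incremental uploads.  The representative is the longest trimmed
    member, ties broken by lexicographically smallest id; group ids are
    numbered by each group's smallest member id, so the result is
    invariant to input order.
    """
    if params is None:
        params = AlignmentParams()
    ids = [s.clone_id for s in seqs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate clone ids: {dup}")
    order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    seqs = [seqs[i] for i in order]
    n = len(seqs)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            _, ev = pairwise_evalue(seqs[i], seqs[j], params)
            if ev < params.evalue_cutoff:
                uf.union(i, j)
    comps: dict[int, list[SeqRecordSSH]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(seqs[i])
    keyed = sorted(comps.values(), key=lambda ms: min(m.clone_id for m in ms))
    groups = []
    for gi, members in enumerate(keyed, start=1):
        rep = min(members, key=lambda m: (-len(m.insert), m.clone_id))
        groups.append(
            RedundantGroup(
                group_id=f"G{gi:04d}",
                members=sorted(members, key=lambda m: m.clone_id),
                representative=rep.clone_id,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Annotation + exports


def read_annotations(path) -> pd.DataFrame:
    """Imported annotation table: clone_id, hit_id, description, evalue, source."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"clone_id", "hit_id", "description", "evalue", "source"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    return df


def assign_priority_annotations(
    groups: list[RedundantGroup],
    annotations: pd.DataFrame | None,
    curation: dict[str, str] | None = None,
    evalue_cutoff: float = 1e-10,
) -> None:
    """Pick each group's priority annotation in place.

    Default: the best imported hit (lowest E-value below the cutoff)
    among any member; a curation mapping (group_id or representative id
    -> text) overrides it, recorded with source 'manual'.
    """
    by_clone: dict[str, pd.DataFrame] = {}
    if annotations is not None:
        known = set()
        for g in groups:
            known.update(g.member_ids)
        unknown = set(annotations["clone_id"]) - known
        if unknown:
            log.warning("annotations for %d unknown clones skipped", len(unknown))
        by_clone = {cid: sub for cid, sub in annotations.groupby("clone_id")}
    for g in groups:
        hits = [by_clone[c] for c in g.member_ids if c in by_clone]
        if hits:
            allhits = pd.concat(hits).sort_values("evalue", kind="mergesort")
            best = allhits.iloc[0]
            if float(best["evalue"]) < evalue_cutoff:
                g.priority_annotation = str(best["description"])
                g.annotation_source = f"imported_{best['source']}"
        if curation:
            override = curation.get(g.group_id) or curation.get(g.representative)
            if override:
                g.priority_annotation = override
                g.annotation_source = "manual"


def merge_annotations_export(
    groups: list[RedundantGroup],
    top_tables: pd.DataFrame | None,
    out_dir,
    annotations: pd.DataFrame | None = None,
    curation: dict[str, str] | None = None,
    what: tuple[str, ...] = ("summary", "fasta", "toptable", "gal"),
    gal_layout=None,
    evalue_cutoff: float = 1e-10,
) -> dict[str, Path]:
    """Write the redundancy-aware exports.

    * ``summary`` — one row per group: representative, member count and
      ids, the representative's ER3/adj p/B/invER2 from the top table,
      and the priority annotation.
    * ``fasta`` — representative inserts with the annotation in the header.
    * ``toptable`` — the top table with an annotation column appended
      ("unsequenced" where the clone is in no group).
    * ``gal`` — the array list with the same annotation column.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assign_priority_annotations(groups, annotations, curation, evalue_cutoff)

    clone_to_group: dict[str, RedundantGroup] = {}
    for g in groups:
        for cid in g.member_ids:
            if cid in clone_to_group:
                raise ValueError(f"clone id {cid} appears in more than one group")
            clone_to_group[cid] = g

    tt = top_tables.set_index("ID") if top_tables is not None else None

    written: dict[str, Path] = {}
    if "summary" in what:
        rows = []
        for g in groups:
            stats = {}
            if tt is not None and g.representative in tt.index:
                r = tt.loc[g.representative]
                stats = {
                    "er3": r["logFC(ER3)"],
                    "adj_p": r["adj.P.Val"],
                    "b_stat": r["B"],
                    "inv_er2": r["invER2"],
                }
            rows.append(
                {
                    "group_id": g.group_id,
                    "representative": g.representative,
                    "member_count": len(g.members),
                    "members": ";".join(g.member_ids),
                    "er3": stats.get("er3", np.nan),
                    "adj_p": stats.get("adj_p", np.nan),
                    "b_stat": stats.get("b_stat", np.nan),
                    "inv_er2": stats.get("inv_er2", np.nan),
                    "priority_annotation": g.priority_annotation,
                    "annotation_source": g.annotation_source,
                }
            )
        p = out_dir / "group_summary.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["summary"] = p
    if "fasta" in what:
        p = out_dir / "representatives.fasta"
        with open(p, "w") as fh:
            for g in groups:
                rep = next(m for m in g.members if m.clone_id == g.representative)
                fh.write(f">{rep.clone_id} group={g.group_id} "
                         f"members={len(g.members)} annotation={g.priority_annotation}\n")
                ins = rep.insert
                for i in range(0, len(ins), 70):
                    fh.write(ins[i : i + 70] + "\n")
        written["fasta"] = p
    if "toptable" in what and tt is not None:
        ann = top_tables.copy()
        ann["annotation"] = [
            clone_to_group[i].priority_annotation if i in clone_to_group else "unsequenced"
            for i in ann["ID"]
        ]
        ann["group_id"] = [
            clone_to_group[i].group_id if i in clone_to_group else ""
            for i in ann["ID"]
        ]
        p = out_dir / "toptable_annotated.tsv"
        ann.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["toptable"] = p
    if "gal" in what and gal_layout is not None:
        gal = gal_layout.spots.copy()
        gal.columns = [c.capitalize() if c != "clone_id" else "ID" for c in gal.columns]
        gal["Annotation"] = [
            clone_to_group[i].priority_annotation if i in clone_to_group else "unsequenced"
            for i in gal["ID"]
        ]
        p = out_dir / "gal_annotated.tsv"
        gal.to_csv(p, sep="\t", index=False)
        written["gal"] = p
    return written
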