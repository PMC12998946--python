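"""Readers and writers: AIRR Rearrangement TSV, FASTA, simulator annotations.

The AIRR Rearrangement format is a tab-delimited table with one row per
chain; paired data are linked by ``cell_id``.  Optional fields that are
unset are written as empty cells (never the string "None").  Columns this
package does not model are preserved opaquely in ``ChainRecord.extra``.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .records import (
    ChainRecord,
    FormatError,
    GermlineSegment,
    GermlineSet,
    PairedCell,
    Repertoire,
    strip_allele,
)

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "junction_aa", "locus")

#: AIRR column -> ChainRecord attribute for directly mapped fields
_COLUMN_MAP = {
    "sequence_id": "sequence_id",
    "locus": "locus",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "junction_aa": "junction_aa",
    "junction": "junction_nt",
    "sequence": "sequence_nt",
    "cdr1_aa": "cdr1_aa",
    "cdr2_aa": "cdr2_aa",
    "cell_id": "cell_id",
    "sample_id": "sample_id",
    "donor_id": "donor_id",
    "cell_subtype": "cell_subtype",
    "true_clone_id": "true_clone_id",
    "clone_id": "clone_id",
}
_INT_COLUMNS = {"shm_count": "shm_count",
                "v_sequence_end": "v_sequence_end",
                "j_sequence_start": "j_sequence_start"}

_WRITE_ORDER = [
    "sequence_id", "locus", "v_call", "d_call", "j_call", "junction_aa",
    "junction", "sequence", "cdr1_aa", "cdr2_aa", "shm_count",
    "v_sequence_end", "j_sequence_start", "cell_id", "sample_id",
    "donor_id", "cell_subtype", "true_clone_id", "clone_id",
]


def _row_to_record(row: dict) -> ChainRecord:
    kwargs = {}
    extra = {}
    for col, value in row.items():
        if value is None or (isinstance(value, float) and pd.isna(value)):
            value = ""
        value = str(value)
        if col in _COLUMN_MAP:
            kwargs[_COLUMN_MAP[col]] = value
        elif col in _INT_COLUMNS:
            kwargs[_INT_COLUMNS[col]] = int(float(value)) if value else None
        else:
            extra[col] = value
    for call_field in ("v_call", "d_call", "j_call"):
        if kwargs.get(call_field):
            kwargs[call_field] = strip_allele(kwargs[call_field])
    for opt in ("sequence_nt", "cdr1_aa", "cdr2_aa", "true_clone_id", "clone_id"):
        if kwargs.get(opt) == "":
            kwargs[opt] = None
    if not kwargs.get("cell_subtype"):
        kwargs["cell_subtype"] = "unknown"
    kwargs["extra"] = extra
    return ChainRecord(**kwargs)


def read_airr(
    path,
    paired: bool = False,
    sample_id: Optional[str] = None,
    collapse_duplicates: bool = False,
    dedup_key: str = "pair",
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    In paired mode rows are grouped by ``cell_id``; cells without exactly
    one heavy and one light chain are rejected (reported in
    ``metadata["rejected_cells"]``), never silently dropped or resolved.

    ``collapse_duplicates`` keeps one representative per identical
    amino-acid sequence within the sample; ``dedup_key`` selects the key
    ("pair" = heavy+light junctions with gene calls, "heavy" = heavy only).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if paired and "cell_id" not in df.columns:
        raise FormatError("missing required column(s): cell_id (paired mode)")

    records = [_row_to_record(row) for row in df.to_dict(orient="records")]
    if sample_id is None:
        sample_id = next((r.sample_id for r in records if r.sample_id), "")

    if not paired:
        rep = Repertoire(sample_id, chains=records)
        if collapse_duplicates:
            rep = _collapse_single(rep)
        return rep

    by_cell: dict[str, list[ChainRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.cell_id not in by_cell:
            order.append(rec.cell_id)
        by_cell.setdefault(rec.cell_id, []).append(rec)

    cells: list[PairedCell] = []
    rejected: list[dict] = []
    for cid in order:
        group = by_cell[cid]
        heavies = [r for r in group if r.locus == "IGH"]
        lights = [r for r in group if r.locus in ("IGK", "IGL")]
        if len(heavies) == 1 and len(lights) == 1:
            cells.append(PairedCell(cid, heavies[0], lights[0]))
        else:
            rejected.append(
                {"cell_id": cid, "n_heavy": len(heavies), "n_light": len(lights)}
            )
    rep = Repertoire(sample_id, cells=cells, metadata={"rejected_cells": rejected})
    if collapse_duplicates:
        rep = _collapse_paired(rep, dedup_key)
    return rep


def _pair_key(cell: PairedCell, dedup_key: str) -> tuple:
    h = cell.heavy
    hk = (h.v_call, h.j_call, h.junction_aa)
    if dedup_key == "heavy":
        return hk
    l = cell.light
    return hk + (l.v_call, l.j_call, l.junction_aa)


def _collapse_paired(rep: Repertoire, dedup_key: str) -> Repertoire:
    seen: set[tuple] = set()
    kept = []
    for cell in rep.cells:
        key = _pair_key(cell, dedup_key)
        if key not in seen:
            seen.add(key)
            kept.append(cell)
    meta = dict(rep.metadata)
    meta["n_collapsed"] = len(rep.cells) - len(kept)
    return Repertoire(rep.sample_id, cells=kept, metadata=meta)


def _collapse_single(rep: Repertoire) -> Repertoire:
    seen: set[tuple] = set()
    kept = []
    for rec in rep.chains:
        key = (rec.locus, rec.v_call, rec.j_call, rec.junction_aa)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    meta = dict(rep.metadata)
    meta["n_collapsed"] = len(rep.chains) - len(kept)
    return Repertoire(rep.sample_id, chains=kept, metadata=meta)


def _record_to_row(rec: ChainRecord) -> dict:
    row = {
        "sequence_id": rec.sequence_id,
        "locus": rec.locus,
        "v_call": rec.v_call,
        "d_call": rec.d_call or "",
        "j_call": rec.j_call,
        "junction_aa": rec.junction_aa,
        "junction": rec.junction_nt or "",
        "sequence": rec.sequence_nt or "",
        "cdr1_aa": rec.cdr1_aa or "",
        "cdr2_aa": rec.cdr2_aa or "",
        "shm_count": "" if rec.shm_count is None else str(rec.shm_count),
        "v_sequence_end": "" if rec.v_sequence_end is None else str(rec.v_sequence_end),
        "j_sequence_start": (
            "" if rec.j_sequence_start is None else str(rec.j_sequence_start)
        ),
        "cell_id": rec.cell_id,
        "sample_id": rec.sample_id,
        "donor_id": rec.donor_id,
        "cell_subtype": rec.cell_subtype,
        "true_clone_id": rec.true_clone_id or "",
        "clone_id": rec.clone_id or "",
    }
    row.update(rec.extra)
    return row


def write_airr(repertoire: Repertoire, path) -> None:
    """Write a repertoire to an AIRR Rearrangement TSV (lossless round trip)."""
    rows = [_record_to_row(r) for r in repertoire.all_chains()]
    extra_cols: list[str] = []
    for row in rows:
        for col in row:
            if col not in _WRITE_ORDER and col not in extra_cols:
                extra_cols.append(col)
    columns = _WRITE_ORDER + extra_cols
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


def write_sim_fasta(records: Iterable[ChainRecord], fasta_path, annot_path) -> None:
    """Write simulator output: FASTA (">locus|cloneID|n") plus annotation TSV.

    The annotation file carries one row per FASTA record, in order, with
    columns chain_type, clone_id, v_sequence_end, j_sequence_start.
    """
    records = list(records)
    missing = [r.sequence_id for r in records if not r.sequence_nt]
    if missing:
        raise FormatError(
            f"records without sequence_nt cannot be written: {missing[:10]}"
        )
    counters: dict[tuple[str, str], int] = {}
    with open(fasta_path, "w") as fa, open(annot_path, "w", newline="") as an:
        writer = csv.writer(an, delimiter="\t")
        writer.writerow(["chain_type", "clone_id", "v_sequence_end", "j_sequence_start"])
        for rec in records:
            clone = rec.true_clone_id or "noise"
            key = (rec.locus, clone)
            counters[key] = counters.get(key, 0) + 1
            fa.write(f">{rec.locus}|{clone}|{counters[key]}\n")
            seq = rec.sequence_nt
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")
            writer.writerow(
                [rec.locus, clone, rec.v_sequence_end or "", rec.j_sequence_start or ""]
            )


def read_germline_fasta(path=None, locus: Optional[str] = None,
                        segment_class: Optional[str] = None) -> GermlineSet:
    """Load a germline set from FASTA (bundled synthetic set by default).

    Headers may be plain segment names (IGHV1-1) or IMGT-style pipe-delimited
    lines (the allele field is used and its allele suffix stripped).  Locus
    and segment class are taken from the name prefix unless given explicitly.
    """
    from Bio import SeqIO

    if path is None:
        path = resources.files("bcrp.data") / "germline_synthetic.fasta"
    gs = GermlineSet()
    with resources.as_file(path) if hasattr(path, "is_file") and not isinstance(
        path, str
    ) else _noop(path) as p:
        for rec in SeqIO.parse(str(p), "fasta"):
            header = rec.description
            name = header.split("|")[1] if "|" in header else header.split()[0]
            name = strip_allele(name)
            loc = locus or name[:3]
            cls = segment_class or name[3]
            gs.add(GermlineSegment(name, loc, cls, str(rec.seq).upper()))
    return gs


class _noop:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_default_germline() -> GermlineSet:
    """The bundled synthetic germline set (20 V / 10 D / 6 J heavy; 15 V / 5 J per light locus)."""
    gs = read_germline_fasta()
    gs.validate_for_simulation()
    return gs
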