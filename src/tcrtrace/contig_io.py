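"""Reading V(D)J contig annotation tables and quality-control screening.

Two input dialects are supported:

* ``tenx_csv`` — 10x Cell Ranger ``filtered_contig_annotations.csv``
  (comma-separated; columns ``barcode, is_cell, high_confidence, chain,
  v_gene, d_gene, j_gene, c_gene, cdr3, productive``).
* ``airr_tsv`` — AIRR Rearrangement TSV (tab-separated; columns ``cell_id,
  locus, v_call, d_call, j_call, c_call, junction_aa, productive``).

QC screens contigs on four criteria, applied in this fixed order so that a
record failing several is attributed deterministically to the first:

1. ``is_cell`` is FALSE            -> reason ``not_cell``
2. ``high_confidence`` is FALSE    -> reason ``low_confidence``
3. chain/locus is not TRA or TRB   -> reason ``wrong_chain``
4. ``productive`` is None          -> reason ``productive_none``

Flag comparison is case-insensitive against the literals ``true``/``false``
(and ``none`` for productive); unrecognized values are treated as failures
of that criterion and logged.  TRD/TRG and multi-locus calls such as
``Multi`` count as ``wrong_chain``: only alpha/beta chains are analyzed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

logger = logging.getLogger("tcrtrace")

DROP_REASONS = ("not_cell", "low_confidence", "wrong_chain", "productive_none")
ACCEPTED_LOCI = ("TRA", "TRB")

TENX_COLUMNS = {
    "barcode": "barcode",
    "is_cell": "is_cell",
    "high_confidence": "high_confidence",
    "chain": "locus",
    "v_gene": "v_call",
    "d_gene": "d_call",
    "j_gene": "j_call",
    "c_gene": "c_call",
    "cdr3": "junction_aa",
    "productive": "productive_raw",
}
AIRR_COLUMNS = {
    "cell_id": "barcode",
    "is_cell": "is_cell",
    "high_confidence": "high_confidence",
    "locus": "locus",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "junction_aa": "junction_aa",
    "productive": "productive_raw",
}
_MANDATORY = {
    "tenx_csv": ("barcode", "is_cell", "high_confidence", "chain",
                 "v_gene", "d_gene", "j_gene", "c_gene", "cdr3", "productive"),
    "airr_tsv": ("cell_id", "locus", "v_call", "d_call", "j_call",
                 "c_call", "junction_aa", "productive"),
}


class ContigFormatError(ValueError):
    """Input table does not conform to the declared dialect."""


@dataclass
class ContigRecord:
    """One contig annotation row, with dialect values preserved verbatim."""

    barcode: str
    is_cell: str
    high_confidence: str
    locus: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    c_call: str = ""
    junction_aa: str = ""
    productive_raw: str = ""
    umis: int | None = None
    contig_id: str = ""


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    n_dropped_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DROP_REASONS}
    )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _clean(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def read_contig_table(path: str | Path, dialect: str) -> list[ContigRecord]:
    """Read a contig annotation table into unified :class:`ContigRecord` rows.

    Raises :class:`ContigFormatError` naming the first missing mandatory
    column; I/O problems propagate as ``OSError``.
    """
    if dialect not in _MANDATORY:
        raise ContigFormatError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "tenx_csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in _MANDATORY[dialect]:
        if col not in table.columns:
            # AIRR files lack the 10x-only flag columns; those are optional
            if dialect == "airr_tsv" and col in ("is_cell", "high_confidence"):
                continue
            raise ContigFormatError(
                f"{path}: missing mandatory column {col!r} for dialect {dialect}"
            )
    colmap = TENX_COLUMNS if dialect == "tenx_csv" else AIRR_COLUMNS
    records: list[ContigRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(table.itertuples(index=False)):
        raw = dict(zip(table.columns, row))
        fields: dict[str, str] = {}
        for src, dst in colmap.items():
            fields[dst] = _clean(raw.get(src, ""))
        if dialect == "airr_tsv":
            # missing 10x flags default to passing values
            fields.setdefault("is_cell", "")
            fields.setdefault("high_confidence", "")
            fields["is_cell"] = fields["is_cell"] or "True"
            fields["high_confidence"] = fields["high_confidence"] or "True"
        umis_raw = _clean(raw.get("umis", raw.get("duplicate_count", "")))
        umis = int(umis_raw) if umis_raw.isdigit() else None
        contig_id = _clean(raw.get("contig_id", raw.get("sequence_id", ""))) or f"contig_{i}"
        if contig_id in seen_ids:
            raise ContigFormatError(f"{path}: duplicate contig_id {contig_id!r}")
        seen_ids.add(contig_id)
        records.append(ContigRecord(umis=umis, contig_id=contig_id, **fields))
    return records


def _flag_fails(value: str, passing: str = "true") -> bool:
    v = value.strip().lower()
    if v == passing:
        return False
    if v not in ("true", "false"):
        logger.warning("unrecognized flag value %r treated as failing", value)
    return True


def _productive_is_none(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "false"):
        return False
    if v != "none":
        logger.warning("unrecognized productive value %r treated as None", value)
    return True


def apply_qc_filters(records: list[ContigRecord]) -> tuple[list[ContigRecord], QcReport]:
    """Apply the four QC criteria; returns kept records and a tally.

    Every record lands either in ``kept`` or in exactly one drop-reason
    bucket (the first failing criterion in the fixed order).
    """
    kept: list[ContigRecord] = []
    report = QcReport(n_input=len(records), n_kept=0)
    for rec in records:
        if _flag_fails(rec.is_cell):
            report.n_dropped_by_reason["not_cell"] += 1
        elif _flag_fails(rec.high_confidence):
            report.n_dropped_by_reason["low_confidence"] += 1
        elif rec.locus.strip() not in ACCEPTED_LOCI:
            report.n_dropped_by_reason["wrong_chain"] += 1
        elif _productive_is_none(rec.productive_raw):
            report.n_dropped_by_reason["productive_none"] += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def write_airr(records: list[ContigRecord], path: str | Path) -> None:
    """Re-emit records as an AIRR Rearrangement TSV."""
    rows = [
        {
            "cell_id": r.barcode,
            "sequence_id": r.contig_id,
            "locus": r.locus,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "c_call": r.c_call,
            "junction_aa": r.junction_aa,
            "productive": r.productive_raw,
            "duplicate_count": "" if r.umis is None else r.umis,
            "is_cell": r.is_cell,
            "high_confidence": r.high_confidence,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
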