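"""Functional/non-functional chain calls and per-cell chain collapse.

A chain is *functional* (F) only if its contig is annotated productive AND
its V call belongs to the functional (non-pseudogene) V table; anything
else is non-functional (N).  ORF-class V genes count as non-functional.

Contigs sharing a barcode are collapsed to the cell's multiset of distinct
chains; distinctness is at full V(D)JC + CDR3 junction resolution, so two
independent rearrangements that reuse the same segments but differ in
junction are kept apart.  Duplicate contigs (identical identity key) keep
the higher-UMI representative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .contig_io import ContigRecord
from .locus_model import UnknownGeneError

logger = logging.getLogger("tcrtrace")


@dataclass(frozen=True, order=True)
class ChainAnnotation:
    locus: str           # TRA / TRB
    v_call: str
    d_call: str          # empty for TRA
    j_call: str
    c_call: str
    junction_aa: str
    status: str          # F / N

    @property
    def identity_key(self) -> tuple[str, str, str, str, str, str]:
        return (self.locus, self.v_call, self.d_call, self.j_call,
                self.c_call, self.junction_aa)


@dataclass(frozen=True)
class CellProfile:
    """One cell's multiset of distinct chains plus locus/status tallies."""

    barcode: str
    chains: tuple[ChainAnnotation, ...]

    @property
    def n_tra_f(self) -> int:
        return sum(1 for c in self.chains if c.locus == "TRA" and c.status == "F")

    @property
    def n_tra_n(self) -> int:
        return sum(1 for c in self.chains if c.locus == "TRA" and c.status == "N")

    @property
    def n_trb_f(self) -> int:
        return sum(1 for c in self.chains if c.locus == "TRB" and c.status == "F")

    @property
    def n_trb_n(self) -> int:
        return sum(1 for c in self.chains if c.locus == "TRB" and c.status == "N")

    @property
    def n_chains(self) -> int:
        return len(self.chains)


def _normalize_productive(value: str) -> bool:
    v = value.strip().lower()
    if v == "true":
        return True
    if v == "false":
        return False
    raise ValueError(
        f"productive value {value!r} should have been screened by QC"
    )


def call_chain_functionality(
    record: ContigRecord,
    functional_v_table: set[str],
    known_genes: set[str] | None = None,
) -> str:
    """Return ``'F'`` or ``'N'`` for one QC-passed contig.

    F requires productive == true and a V call in the functional-gene
    table.  An empty V call is retained as N (with a warning): the chain
    still occupies a slot in the cell's pattern.  A non-empty V call that
    resolves nowhere in the locus model raises :class:`UnknownGeneError`
    when ``known_genes`` is supplied.
    """
    productive = _normalize_productive(record.productive_raw)
    v = record.v_call.strip().split("*")[0].replace("/", "")
    if not v:
        logger.warning("contig %s has no V call; retained as N", record.contig_id)
        return "N"
    if known_genes is not None and v not in known_genes:
        base = v.split("/")[0]
        if base not in known_genes:
            raise UnknownGeneError(f"V call {record.v_call!r} not in locus model")
    return "F" if productive and v in functional_v_table else "N"


def _to_chain(record: ContigRecord, functional_v_table: set[str],
              known_genes: set[str] | None) -> ChainAnnotation:
    status = call_chain_functionality(record, functional_v_table, known_genes)
    clean = lambda s: s.strip().split("*")[0]
    return ChainAnnotation(
        locus=record.locus.strip(),
        v_call=clean(record.v_call).replace("/", ""),
        d_call=clean(record.d_call),
        j_call=clean(record.j_call),
        c_call=clean(record.c_call),
        junction_aa=record.junction_aa.strip(),
        status=status,
    )


def collapse_cell_chains(
    records: list[ContigRecord],
    functional_v_table: set[str],
    known_genes: set[str] | None = None,
) -> CellProfile:
    """Collapse one barcode's QC-passed contigs into a :class:`CellProfile`.

    Contigs with identical identity key (locus, V, D, J, C, junction)
    collapse to one chain, keeping the larger-UMI representative; the
    result is order-independent in the input records.
    """
    if not records:
        raise ValueError("cannot build a cell profile from zero contigs")
    barcodes = {r.barcode for r in records}
    if len(barcodes) != 1:
        raise ValueError(f"records span multiple barcodes: {sorted(barcodes)}")
    best: dict[tuple, tuple[int, ChainAnnotation]] = {}
    for rec in records:
        chain = _to_chain(rec, functional_v_table, known_genes)
        key = chain.identity_key
        umis = rec.umis if rec.umis is not None else -1
        # keep the larger-UMI contig; exact ties break on the chain tuple
        # itself so the collapse is order-independent
        if key not in best or (umis, chain) > best[key]:
            best[key] = (umis, chain)
    chains = tuple(sorted(c for _, c in best.values()))
    return CellProfile(barcode=records[0].barcode, chains=chains)


def group_by_barcode(records: list[ContigRecord]) -> dict[str, list[ContigRecord]]:
    """Bucket QC-passed contigs by cell barcode, preserving input order."""
    buckets: dict[str, list[ContigRecord]] = {}
    for rec in records:
        buckets.setdefault(rec.barcode, []).append(rec)
    return buckets


def build_profiles(
    records: list[ContigRecord],
    functional_v_table: set[str],
    known_genes: set[str] | None = None,
) -> list[CellProfile]:
    """Collapse a full sample of QC-passed contigs into per-cell profiles."""
    return [
        collapse_cell_chains(recs, functional_v_table, known_genes)
        for recs in group_by_barcode(records).values()
    ]


def unique_sequence_count(profiles: list[CellProfile]) -> int:
    """Distinct chain identity keys across a sample's cells."""
    keys = Counter(c.identity_key for p in profiles for c in p.chains)
    return len(keys)
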