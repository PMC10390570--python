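"""Same-chromosome mechanism inference for multi-rearrangement cells.

A T cell has two homologous chromosomes per locus, so two distinct
same-locus rearrangements are always explainable biallelically.  Three or
more — and some informative pairs — require a *same-chromosome* mechanism:

* ``trec_circle_beta`` / ``trec_circle_alpha`` — a first complete
  rearrangement is excised intact onto a TREC circle by a second,
  positionally "outer" rearrangement on the same chromosome, and the
  circle-resident join is still transcribed.  For TRB this forces the
  circle-resident event into the upstream D-J-C cluster (DJC1) and the
  chromosome-resident event into DJC2 with a strictly more 5' V; for TRA
  the chromosome-resident V-J excision interval must strictly contain the
  circle-resident join (more 5' V and more 3' J).
* ``inversion_v30`` — the single reverse-orientation V (human TRBV30,
  mouse TRBV31) joins by inversion, which retains the intervening DNA, so
  a deletional DJC1 join and the inversional DJC2 join can coexist on one
  chromosome.
* ``two_chromosomes`` — ordinary biallelic rearrangement; always feasible
  for up to two same-locus events.
* ``unexplained`` — no assignment of events to at most two chromosomes
  (with the mechanisms above) covers the observed set.

The rule-based pair predicates are cross-checked against
:func:`brute_force_excision_oracle`, a direct simulation of the locus as an
ordinal segment sequence in which deletional joins excise the intervening
interval onto a circle and inversional joins invert it in place.
Chronology is unobservable in transcript data, so the circle-resident role
is inferred purely from positional feasibility.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .chain_model import CellProfile, ChainAnnotation
from .locus_model import LocusGene, LocusMap, UnknownGeneError, rss_compatible

logger = logging.getLogger("tcrtrace")

MECHANISMS = (
    "trec_circle_beta", "trec_circle_alpha", "inversion_v30",
    "two_chromosomes", "unexplained",
)


@dataclass(frozen=True)
class RearrangementEvent:
    """One resolved V(D)J rearrangement of a cell, tied to a locus map."""

    locus: str
    v_call: str
    j_call: str
    d_call: str = ""      # TRB only; inferred from the J/C cluster if absent
    c_call: str = ""
    status: str = "F"

    def genes(self, locus_map: LocusMap) -> tuple[LocusGene, ...]:
        v = locus_map.resolve(self.v_call)
        j = locus_map.resolve(self.j_call)
        if self.locus == "TRB":
            d = locus_map.resolve(self.d_call)
            return (v, d, j)
        return (v, j)


def event_from_chain(chain: ChainAnnotation, locus_map: LocusMap) -> RearrangementEvent:
    """Resolve a chain annotation into a rearrangement event.

    For TRB contigs lacking a D call, the cluster is inferred from the J
    call (J1-x implies TRBD1, J2-x implies TRBD2), using the C call as
    corroborating evidence when present; the cluster's D segment is then
    assiged.  A J/C cluster mismatch raises ``ValueError``.
    """
    v = locus_map.resolve(chain.v_call) if chain.v_call else None
    j = locus_map.resolve(chain.j_call) if chain.j_call else None
    if v is None or j is None:
        raise UnknownGeneError(
            f"chain {chain.identity_key} lacks a resolvable V or J call"
        )
    d_name = ""
    if chain.locus == "TRB":
        if chain.c_call:
            c = locus_map.resolve(chain.c_call)
            if c.cluster != j.cluster:
                raise ValueError(
                    f"J {j.name} (cluster {j.cluster}) inconsistent with "
                    f"C {c.name} (cluster {c.cluster})"
                )
        if chain.d_call:
            d_name = locus_map.resolve(chain.d_call).name
        else:
            ds = locus_map.segments("D", cluster=j.cluster)
            d_name = ds[0].name
            logger.debug("inferred %s for D-less TRB chain via cluster %s",
                         d_name, j.cluster)
    return RearrangementEvent(
        locus=chain.locus, v_call=v.name, d_call=d_name,
        j_call=j.name, c_call=chain.c_call, status=chain.status,
    )


# ---------------------------------------------------------------------------
# Rule-based pair predicates
# ---------------------------------------------------------------------------

def trb_trec_compatible(a: RearrangementEvent, b: RearrangementEvent,
                        locus_map: LocusMap) -> bool:
    """Can TRB event ``a`` ride a TREC circle excised by TRB event ``b``?

    Requires: a in cluster DJC1, b in cluster DJC2, b's V strictly upstream
    of a's V, both V segments forward, and 12/23-legal joins — then b's
    V->D2 excision interval contains a's complete V-D1-J1 join.
    """
    if a.locus != "TRB" or b.locus != "TRB":
        raise ValueError("trb_trec_compatible requires two TRB events")
    va, da, ja = a.genes(locus_map)
    vb, db, jb = b.genes(locus_map)
    if va.name == vb.name or da.name == db.name or ja.name == jb.name:
        return False
    if da.cluster != "DJC1" or ja.cluster != "DJC1":
        return False
    if db.cluster != "DJC2" or jb.cluster != "DJC2":
        return False
    if va.orientation != "forward" or vb.orientation != "forward":
        return False
    if not vb.ordinal < va.ordinal:
        return False
    return all((
        rss_compatible(va, da), rss_compatible(da, ja),
        rss_compatible(vb, db), rss_compatible(db, jb),
    ))


def tra_trec_compatible(a: RearrangementEvent, b: RearrangementEvent,
                        locus_map: LocusMap) -> bool:
    """Can TRA event ``a`` ride a TREC circle excised by TRA event ``b``?

    Requires b's V strictly upstream of a's V and b's J strictly downstream
    of a's J, so b's V->J excision interval strictly contains a's join.
    """
    if a.locus != "TRA" or b.locus != "TRA":
        raise ValueError("tra_trec_compatible requires two TRA events")
    va, ja = a.genes(locus_map)
    vb, jb = b.genes(locus_map)
    if va.name == vb.name or ja.name == jb.name:
        return False
    if va.orientation != "forward" or vb.orientation != "forward":
        return False
    if not (vb.ordinal < va.ordinal and jb.ordinal > ja.ordinal):
        return False
    return rss_compatible(va, ja) and rss_compatible(vb, jb)


def trb_inversion_compatible(a: RearrangementEvent, b: RearrangementEvent,
                             locus_map: LocusMap) -> bool:
    """Can two TRB events coexist on one chromosome via the reverse V?

    Exactly one event must use the locus's reverse-orientation V (human
    TRBV30 / mouse TRBV31); that inversional event must use cluster DJC2
    and the deletional partner cluster DJC1 (a forward V joining D2 first
    would delete cluster 1, and an inversional join onto D1 first leaves
    cluster 2 inverted and unusable).  Symmetric in its arguments.
    """
    if a.locus != "TRB" or b.locus != "TRB":
        raise ValueError("trb_inversion_compatible requires two TRB events")
    va, da, ja = a.genes(locus_map)
    vb, db, jb = b.genes(locus_map)
    if va.name == vb.name or da.name == db.name or ja.name == jb.name:
        return False
    rev_a = va.orientation == "reverse"
    rev_b = vb.orientation == "reverse"
    if rev_a == rev_b:
        return False
    (vr, dr, jr), (vf, df, jf) = ((va, da, ja), (vb, db, jb)) if rev_a else \
                                 ((vb, db, jb), (va, da, ja))
    if vf.orientation != "forward":
        return False
    if dr.cluster != "DJC2" or jr.cluster != "DJC2":
        return False
    if df.cluster != "DJC1" or jf.cluster != "DJC1":
        return False
    return all((
        rss_compatible(vr, dr), rss_compatible(dr, jr),
        rss_compatible(vf, df), rss_compatible(df, jf),
    ))


# ---------------------------------------------------------------------------
# Brute-force excision oracle
# ---------------------------------------------------------------------------

class _Seg:
    __slots__ = ("gene", "forward")

    def __init__(self, gene: LocusGene, forward: bool):
        self.gene = gene
        self.forward = forward


class _Block:
    """A completed coding join; atomic thereafter."""

    __slots__ = ("event_index",)

    def __init__(self, event_index: int):
        self.event_index = event_index


def _find_raw(chrom: list, name: str) -> int | None:
    for i, el in enumerate(chrom):
        if isinstance(el, _Seg) and el.gene.name == name:
            return i
    return None


def _deletional_join(chrom: list, circles: list, i_up: int, i_down: int,
                     block: _Block) -> list:
    """Join elements at i_up and i_down, excising the open interval."""
    circle = chrom[i_up + 1:i_down]
    if circle:
        circles.append(circle)
    return chrom[:i_up] + [block] + chrom[i_down + 1:]


def _apply_event(chrom: list, circles: list, event: RearrangementEvent,
                 eidx: int, locus_map: LocusMap) -> list | None:
    """Apply one rearrangement; returns the new chromosome or None if illegal."""
    genes = event.genes(locus_map)
    if event.locus == "TRB":
        v, d, j = genes
    else:
        v, j = genes
        d = None

    block = _Block(eidx)
    if d is not None:
        # step 1: D-J deletional join (both forward, D upstream of J)
        pd_, pj = _find_raw(chrom, d.name), _find_raw(chrom, j.name)
        if pd_ is None or pj is None or pd_ >= pj:
            return None
        if not (chrom[pd_].forward and chrom[pj].forward):
            return None
        if not rss_compatible(d, j):
            return None
        chrom = _deletional_join(chrom, circles, pd_, pj, block)
        target = d        # V joins the block via D's 5' RSS
    else:
        target = j

    # step 2: V join onto the block (or directly onto J for TRA)
    if d is None:
        pv, pt = _find_raw(chrom, v.name), _find_raw(chrom, j.name)
        if pt is None:
            return None
        if not rss_compatible(v, j):
            return None
        block_pos = None
    else:
        pv = _find_raw(chrom, v.name)
        block_pos = chrom.index(block)
        pt = block_pos
        if not rss_compatible(v, d):
            return None
    if pv is None:
        return None
    v_el = chrom[pv]
    if v_el.forward:
        # deletional geometry: V strictly upstream of its target
        if pv >= pt:
            return None
        if d is None:
            if not chrom[pt].forward:
                return None
            chrom = _deletional_join(chrom, circles, pv, pt, block)
        else:
            circle = chrom[pv + 1:pt]
            if circle:
                circles.append(circle)
            chrom = chrom[:pv] + [block] + chrom[pt + 1:]
        return chrom
    # inversional geometry: reverse V strictly downstream of its target;
    # the intervening DNA is inverted in place, nothing is excised
    if pv <= pt:
        return None
    mid = chrom[pt + 1:pv]
    for el in mid:
        if isinstance(el, _Seg):
            el.forward = not el.forward
    return chrom[:pt] + [block] + mid[::-1] + chrom[pv + 1:]


def brute_force_excision_oracle(
    events: list[RearrangementEvent],
    locus_map: LocusMap,
    scheme: list[list[int]],
) -> bool:
    """Simulate a scheme: events assigned to chromosomes, in temporal order.

    ``scheme`` lists, per chromosome, the indices into ``events`` in the
    order the rearrangements occur.  Each chromosome starts as a fresh copy
    of the full locus.  Deletional joins excise the open interval between
    the joined segments onto a circle; inversional joins (the reverse V)
    invert it in place.  Returns True iff every event's complete join ends
    up intact on a final chromosome or on one excised circle, with each
    physical segment used at most once.
    """
    flat = [i for chrom_events in scheme for i in chrom_events]
    if sorted(flat) != sorted(set(flat)) or any(
        i < 0 or i >= len(events) for i in flat
    ):
        raise ValueError("scheme must reference each event index at most once")
    if len(scheme) > 2:
        return False
    for chrom_events in scheme:
        chrom: list = [
            _Seg(g, g.orientation == "forward") for g in locus_map.genes
        ]
        circles: list = []
        for eidx in chrom_events:
            result = _apply_event(chrom, circles, events[eidx], eidx, locus_map)
            if result is None:
                return False
            chrom = result
    return True


def oracle_feasible_pair(a: RearrangementEvent, b: RearrangementEvent,
                         locus_map: LocusMap, order: tuple[int, int] = (0, 1)) -> bool:
    """Oracle feasibility of two events on ONE chromosome in a given order."""
    return brute_force_excision_oracle([a, b], locus_map, [list(order)])


# ---------------------------------------------------------------------------
# Cell-level mechanism calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanismRole:
    mechanism: str
    locus: str
    circle: RearrangementEvent       # circle-resident / reverse-V event
    chromosome: RearrangementEvent   # chromosome-resident / deletional partner


@dataclass
class MechanismCall:
    barcode: str
    feasible: frozenset[str]
    roles: tuple[MechanismRole, ...] = ()
    per_locus: dict[str, frozenset[str]] = field(default_factory=dict)


def _pair_mechanisms(a: RearrangementEvent, b: RearrangementEvent,
                     locus_map: LocusMap) -> list[MechanismRole]:
    """All same-chromosome mechanisms (with roles) for an unordered pair."""
    roles: list[MechanismRole] = []
    if a.locus == "TRB":
        for first, second in ((a, b), (b, a)):
            if trb_trec_compatible(first, second, locus_map):
                roles.append(MechanismRole("trec_circle_beta", "TRB", first, second))
        if trb_inversion_compatible(a, b, locus_map):
            va = locus_map.resolve(a.v_call)
            rev, fwd = (a, b) if va.orientation == "reverse" else (b, a)
            roles.append(MechanismRole("inversion_v30", "TRB", rev, fwd))
    else:
        for first, second in ((a, b), (b, a)):
            if tra_trec_compatible(first, second, locus_map):
                roles.append(MechanismRole("trec_circle_alpha", "TRA", first, second))
    return roles


def _chain_feasible(events: list[RearrangementEvent], locus_map: LocusMap
                    ) -> list[MechanismRole] | None:
    """Feasibility of >=3 same-locus events on ONE chromosome.

    Only nested TRA TREC chains qualify (each join strictly inside the
    next excision); TRB is capped at two events per chromosome by its two
    D clusters.
    """
    if events[0].locus == "TRB":
        return None
    ordered = sorted(events, key=lambda e: locus_map.resolve(e.v_call).ordinal,
                     reverse=True)   # innermost (most 3' V) first
    roles = []
    for inner, outer in zip(ordered, ordered[1:]):
        if not tra_trec_compatible(inner, outer, locus_map):
            return None
        roles.append(MechanismRole("trec_circle_alpha", "TRA", inner, outer))
    return roles


def _partitions_two(indices: list[int]):
    """All unordered partitions of indices into at most two nonempty parts."""
    yield [indices]
    n = len(indices)
    for mask in range(1, 2 ** (n - 1)):
        part1 = [indices[i] for i in range(n) if mask >> i & 1]
        part2 = [i for i in indices if i not in part1]
        if part2:
            yield [part1, part2]


def _locus_feasible(events: list[RearrangementEvent], locus_map: LocusMap
                    ) -> tuple[frozenset[str], list[MechanismRole]]:
    """Mechanism set and role assignments for one locus's events."""
    n = len(events)
    if n == 1:
        return frozenset(), []
    mechanisms: set[str] = set()
    roles: list[MechanismRole] = []
    covered = False
    for partition in _partitions_two(list(range(n))):
        part_roles: list[MechanismRole] = []
        ok = True
        for part in partition:
            if len(part) == 1:
                continue
            evs = [events[i] for i in part]
            if len(part) == 2:
                pr = _pair_mechanisms(evs[0], evs[1], locus_map)
            else:
                pr = _chain_feasible(evs, locus_map)
            if not pr:
                ok = False
                break
            part_roles.extend(pr)
        if ok:
            covered = True
            if all(len(part) == 1 for part in partition):
                mechanisms.add("two_chromosomes")
            for r in part_roles:
                mechanisms.add(r.mechanism)
                if r not in roles:
                    roles.append(r)
    if not covered:
        mechanisms = {"unexplained"}
        roles = []
    return frozenset(mechanisms), roles


def classify_cell_mechanism(
    profile: CellProfile,
    maps: dict[str, LocusMap],
) -> MechanismCall:
    """Mechanism call for a cell with multiple same-locus rearrangements.

    ``maps`` supplies the species' locus maps keyed by ``'TRA'``/``'TRB'``.
    Loci with a single event contribute nothing; per-locus results are
    combined by union.
    """
    per_locus: dict[str, frozenset[str]] = {}
    roles: list[MechanismRole] = []
    for locus in ("TRA", "TRB"):
        chains = [c for c in profile.chains if c.locus == locus]
        if len(chains) < 2:
            continue
        locus_map = maps[locus]
        events = [event_from_chain(c, locus_map) for c in chains]
        mechanisms, locus_roles = _locus_feasible(events, locus_map)
        per_locus[locus] = mechanisms
        roles.extend(locus_roles)
    feasible = frozenset().union(*per_locus.values()) if per_locus else frozenset()
    return MechanismCall(
        barcode=profile.barcode,
        feasible=feasible,
        roles=tuple(roles),
        per_locus=per_locus,
    )


def mechanism_table(calls: list[MechanismCall]) -> pd.DataFrame:
    """Mechanism-call table: one row per cell x locus."""
    rows = []
    for call in calls:
        for locus, mechanisms in call.per_locus.items():
            rows.append({
                "barcode": call.barcode,
                "locus": locus,
                "feasible_mechanisms": ";".join(sorted(mechanisms)),
                "roles": ";".join(
                    f"{r.mechanism}[circle={r.circle.v_call},"
                    f"chrom={r.chromosome.v_call}]"
                    for r in call.roles if r.locus == locus
                ),
            })
    return pd.DataFrame(rows, columns=["barcode", "locus",
                                       "feasible_mechanisms", "roles"])
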