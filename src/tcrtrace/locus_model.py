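"""Ordinal topology model of the TRA and TRB loci.

The mechanism logic downstream (TREC-circle traceability, inversional
rearrangement) only needs *relative* segment order, transcriptional
orientation, D-J-C cluster membership and the recombination-signal-sequence
(RSS) spacer class of each segment end.  Positions are therefore stored as
ordinals rather than base-pair coordinates, which also decouples the tables
from any particular genome assembly.

Packaged tables follow the IMGT reference gene order for human and mouse
TRA/TRB.  Key topological facts encoded:

* TRB carries two tandem D-J-C clusters (TRBD1-TRBJ1.x-TRBC1 and
  TRBD2-TRBJ2.x-TRBC2) downstream of the V array.
* Exactly one V segment per TRB locus lies downstream of TRBC2 in reverse
  transcriptional orientation (human TRBV30, mouse TRBV31); it rearranges by
  inversion rather than deletion.
* TRA J segments are numbered against genomic order: TRAJ61 is the most 5'
  J, TRAJ1 the most 3'.
* RSS spacers: V segments carry a 23-spacer RSS 3' of the coding region,
  D segments a 12-spacer 5' and a 23-spacer 3', J segments a 12-spacer 5'.
  Joins must pair one 12-spacer with one 23-spacer (the 12/23 rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger("tcrtrace")

SPECIES = ("human", "mouse")
LOCI = ("TRA", "TRB")

_SCHEMA = [
    "name", "segment_class", "ordinal", "orientation", "cluster",
    "rss_5p", "rss_3p", "functionality",
]
_SEGMENT_CLASSES = {"V", "D", "J", "C"}
_ORIENTATIONS = {"forward", "reverse"}
_CLUSTERS = {"none", "DJC1", "DJC2"}
_RSS = {"none", "spacer12", "spacer23"}
_FUNCTIONALITY = {"F", "ORF", "P"}


class LocusModelError(ValueError):
    """Packaged or user locus table violates the schema or an invariant."""


class UnknownGeneError(KeyError):
    """A gene call does not resolve against the locus map."""


@dataclass(frozen=True)
class LocusGene:
    name: str
    species: str
    locus: str
    segment_class: str   # V / D / J / C
    ordinal: int         # strictly increasing 5'->3'
    orientation: str     # forward / reverse
    cluster: str         # none / DJC1 / DJC2
    rss_5p: str          # none / spacer12 / spacer23
    rss_3p: str
    functionality: str   # F / ORF / P


@dataclass
class LocusMap:
    species: str
    locus: str
    genes: list[LocusGene]
    _by_name: dict[str, LocusGene] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_name:
            self._by_name = {g.name: g for g in self.genes}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_table(cls, table: pd.DataFrame, species: str, locus: str) -> "LocusMap":
        missing = [c for c in _SCHEMA if c not in table.columns]
        if missing:
            raise LocusModelError(f"locus table missing columns: {missing}")
        genes = [
            LocusGene(
                name=str(r["name"]),
                species=species,
                locus=locus,
                segment_class=str(r["segment_class"]),
                ordinal=int(r["ordinal"]),
                orientation=str(r["orientation"]),
                cluster=str(r["cluster"]),
                rss_5p=str(r["rss_5p"]),
                rss_3p=str(r["rss_3p"]),
                functionality=str(r["functionality"]),
            )
            for _, r in table.iterrows()
        ]
        return cls(species=species, locus=locus, genes=genes)

    def _validate(self) -> None:
        seen: set[int] = set()
        prev = None
        for g in self.genes:
            if g.segment_class not in _SEGMENT_CLASSES:
                raise LocusModelError(f"{g.name}: bad segment_class {g.segment_class!r}")
            if g.orientation not in _ORIENTATIONS:
                raise LocusModelError(f"{g.name}: bad orientation {g.orientation!r}")
            if g.cluster not in _CLUSTERS:
                raise LocusModelError(f"{g.name}: bad cluster {g.cluster!r}")
            if g.rss_5p not in _RSS or g.rss_3p not in _RSS:
                raise LocusModelError(f"{g.name}: bad RSS class")
            if g.functionality not in _FUNCTIONALITY:
                raise LocusModelError(f"{g.name}: bad functionality {g.functionality!r}")
            if g.ordinal in seen or (prev is not None and g.ordinal <= prev):
                raise LocusModelError(
                    f"ordinals not strictly increasing at {g.name} "
                    f"({self.species} {self.locus})"
                )
            seen.add(g.ordinal)
            prev = g.ordinal
        if len(self._by_name) != len(self.genes):
            raise LocusModelError(f"duplicate gene names in {self.species} {self.locus}")
        if self.locus == "TRB":
            rev = [g for g in self.genes if g.segment_class == "V" and g.orientation == "reverse"]
            if len(rev) != 1:
                raise LocusModelError(
                    f"{self.species} TRB must carry exactly one reverse V, found {len(rev)}"
                )
            c2 = [g for g in self.genes if g.name.endswith("C2")]
            if c2 and rev[0].ordinal <= c2[0].ordinal:
                raise LocusModelError("reverse V must lie downstream of the second C")

    # -- lookup -----------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> LocusGene:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownGeneError(
                f"gene {name!r} not in {self.species} {self.locus} locus map"
            ) from None

    def resolve(self, call: str) -> LocusGene:
        """Resolve a raw gene call (allele suffixes, ambiguous calls) to a gene."""
        return self.get(normalize_gene_name(call, self))

    @property
    def names(self) -> set[str]:
        return set(self._by_name)

    @property
    def reverse_v(self) -> LocusGene | None:
        for g in self.genes:
            if g.segment_class == "V" and g.orientation == "reverse":
                return g
        return None

    def segments(self, segment_class: str, cluster: str | None = None,
                 functionality: str | None = None) -> list[LocusGene]:
        out = [g for g in self.genes if g.segment_class == segment_class]
        if cluster is not None:
            out = [g for g in out if g.cluster == cluster]
        if functionality is not None:
            out = [g for g in out if g.functionality == functionality]
        return out


def _data_path(species: str, locus: str):
    return resources.files("tcrtrace.data").joinpath(f"{species}_{locus}.tsv")


_CACHE: dict[tuple[str, str], LocusMap] = {}


def load_locus(species: str, locus: str) -> LocusMap:
    """Load the packaged locus map for one species and locus.

    ``species='toy'`` with ``locus='TRB'`` loads a reduced 12-segment locus
    (3 forward V, one reverse V, two 2-J D-J-C clusters) used as the
    exhaustive test bed for the excision oracle.
    """
    if species not in SPECIES + ("toy",) or locus not in LOCI:
        raise LocusModelError(f"unsupported species/locus: {species}/{locus}")
    key = (species, locus)
    if key not in _CACHE:
        path = _data_path(species, locus)
        with resources.as_file(path) as p:
            table = pd.read_csv(p, sep="\t", dtype=str)
        table["ordinal"] = table["ordinal"].astype(int)
        _CACHE[key] = LocusMap.from_table(table, species=species, locus=locus)
    return _CACHE[key]


def normalize_gene_name(call: str, locus_map: LocusMap) -> str:
    """Normalize a raw annotation gene call to a packaged gene name.

    Strips allele suffixes (``TRBV19*01`` -> ``TRBV19``), removes the slash
    of dual TRAV/DV names (``TRAV14/DV4`` -> ``TRAV14DV4``), and maps
    ambiguous multi-gene calls (``TRBV12-3/12-4``) to the 5'-most member
    with a warning.
    """
    name = call.strip().split("*")[0]
    if name in locus_map:
        return name
    if "/" in name:
        collapsed = name.replace("/", "")
        if collapsed in locus_map:
            return collapsed
        parts = name.split("/")
        head = parts[0]
        prefix = head[: next((i for i, ch in enumerate(head) if ch.isdigit()), len(head))]
        candidates = [head] + [p if p.startswith(prefix) else prefix + p for p in parts[1:]]
        resolved = [locus_map.get(c) for c in candidates if c in locus_map]
        if resolved:
            best = min(resolved, key=lambda g: g.ordinal)
            logger.warning(
                "ambiguous gene call %r mapped to 5'-most member %s", call, best.name
            )
            return best.name
    raise UnknownGeneError(
        f"gene call {call!r} not in {locus_map.species} {locus_map.locus} locus map"
    )


def upstream_of(a: str, b: str, locus_map: LocusMap) -> bool:
    """True iff gene ``a`` lies strictly 5' of gene ``b`` on the locus."""
    return locus_map.get(a).ordinal < locus_map.get(b).ordinal


def rss_compatible(a: LocusGene, b: LocusGene, join: str = "a3_to_b5") -> bool:
    """12/23 rule for a join of a's 3' RSS onto b's 5' RSS.

    True iff the two facing RSSs pair one 12-spacer with one 23-spacer.
    Segments lacking the facing RSS (e.g. C genes) are never compatible.
    """
    if join != "a3_to_b5":
        raise ValueError(f"unsupported join geometry: {join}")
    pair = {a.rss_3p, b.rss_5p}
    return pair == {"spacer12", "spacer23"}


def functional_v_genes(species: str, locus: str | None = None) -> set[str]:
    """Names of IMGT-functional V segments ('no pseudogene family').

    ORF-class genes are excluded (conservative) and logged once at call.
    """
    loci = [locus] if locus else list(LOCI)
    out: set[str] = set()
    orf: set[str] = set()
    for loc in loci:
        lm = load_locus(species, loc)
        for g in lm.segments("V"):
            if g.functionality == "F":
                out.add(g.name)
            elif g.functionality == "ORF":
                orf.add(g.name)
    if orf:
        logger.debug("ORF-class V genes treated as non-functional: %s", sorted(orf))
    return out


def known_gene_names(species: str) -> set[str]:
    """All gene names across both loci for a species (for unknown-call checks)."""
    names: set[str] = set()
    for loc in LOCI:
        names |= load_locus(species, loc).names
    return names
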