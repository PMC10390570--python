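"""Synthetic 10x-style contig tables with full truth labels.

The generator emulates the statistical structure the analysis assumes in
real V(D)J data: per-cell chain multisets drawn from configured pattern
frequencies, locus-consistent V/(D)/J/C draws from the packaged locus
maps (cluster-consistent D/J/C for TRB), functional and non-functional
chains, QC-noise rows exercising each screening criterion, and planted
multi-chain cells whose gene combinations are verified mechanism-feasible
against the excision oracle at generation time.

It does *not* model transcript/UMI depth, doublets, ambient contamination,
or biological junction sequences (CDR3s are random amino-acid strings that
only serve to keep identity keys distinct), and default gene usage is
uniform over functional genes rather than the skewed usage of real
repertoires.

Default pattern weights approximate a thymus-like mix: two-chain cells
dominate with beta(F)+alpha(F) the most frequent combination, single-chain
cells led by beta(F), and a small tail of three-plus-chain cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_patterns
from .chain_model import CellProfile, ChainAnnotation
from .contig_io import DROP_REASONS
from .locus_model import LocusMap, load_locus
from .traceability import (
    RearrangementEvent,
    brute_force_excision_oracle,
    event_from_chain,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Default per-pattern weights (codes 1..23).  Chosen to resemble the
#: published thymus mix: ~15% single-chain, ~60% two-chain dominated by
#: beta(F)+alpha(F), ~25% three-plus.  See docs/methods.md.
DEFAULT_PATTERN_WEIGHTS: tuple[float, ...] = (
    0.050, 0.020, 0.030, 0.015,            # 1-4   singles
    0.020, 0.015, 0.008,                   # 5-7   two beta
    0.015, 0.012, 0.006,                   # 8-10  two alpha
    0.350, 0.060, 0.050, 0.030,            # 11-14 beta+alpha
    0.004, 0.006, 0.006, 0.003,            # 15-18 three beta
    0.004, 0.006, 0.006, 0.003,            # 19-22 three alpha
    0.281,                                 # 23    others
)


@dataclass
class SynthConfig:
    n_cells: int = 5000
    pattern_weights: tuple[float, ...] = DEFAULT_PATTERN_WEIGHTS
    mechanism_plant_rates: dict[str, float] = field(default_factory=dict)
    qc_noise: dict[str, float] = field(default_factory=dict)  # reason -> proportion
    species: str = "human"
    seed: int = 0
    dialect: str = "tenx_csv"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if len(self.pattern_weights) != 23:
            raise ValueError("pattern_weights must have 23 entries")
        if any(w < 0 for w in self.pattern_weights) or sum(self.pattern_weights) <= 0:
            raise ValueError("pattern_weights must be nonnegative and normalizable")
        if self.species not in ("human", "mouse"):
            raise ValueError(f"unsupported species {self.species!r}")
        if self.dialect not in ("tenx_csv", "airr_tsv"):
            raise ValueError(f"unsupported dialect {self.dialect!r}")
        bad = set(self.qc_noise) - set(DROP_REASONS)
        if bad:
            raise ValueError(f"unknown qc_noise reasons: {sorted(bad)}")
        for m in self.mechanism_plant_rates:
            if m not in ("trec_circle_beta", "trec_circle_alpha", "inversion_v30"):
                raise ValueError(f"cannot plant mechanism {m!r}")


# ---------------------------------------------------------------------------
# chain draws
# ---------------------------------------------------------------------------

def _junction(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    return "C" + "".join(rng.choice(_AA, size=length - 2)) + "F"


def _draw_chain(rng: np.random.Generator, locus: str, status: str,
                maps: dict[str, LocusMap]) -> ChainAnnotation:
    lm = maps[locus]
    if status == "F":
        v = _choice(rng, lm.segments("V", functionality="F"))
        productive = True
    else:
        # non-functional: either a non-productive contig with a functional V
        # or a productive contig using a pseudogene V
        pseudos = lm.segments("V", functionality="P")
        if pseudos and rng.random() < 0.3:
            v = _choice(rng, pseudos)
            productive = True
        else:
            v = _choice(rng, [g for g in lm.segments("V")
                              if g.functionality == "F"])
            productive = False
    if locus == "TRB":
        cluster = "DJC1" if rng.random() < 0.5 else "DJC2"
        d = lm.segments("D", cluster=cluster)[0]
        j = _choice(rng, lm.segments("J", cluster=cluster, functionality="F"))
        c = lm.segments("C", cluster=cluster)[0]
        d_call, c_call = d.name, c.name
    else:
        j = _choice(rng, lm.segments("J", functionality="F"))
        d_call, c_call = "", "TRAC"
    return ChainAnnotation(
        locus=locus, v_call=v.name, d_call=d_call, j_call=j.name,
        c_call=c_call, junction_aa=_junction(rng), status=status,
    ), productive


def _choice(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


_PATTERN_MULTISETS: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("TRB", "F"),),
    2: (("TRB", "N"),),
    3: (("TRA", "F"),),
    4: (("TRA", "N"),),
    5: (("TRB", "F"), ("TRB", "F")),
    6: (("TRB", "F"), ("TRB", "N")),
    7: (("TRB", "N"), ("TRB", "N")),
    8: (("TRA", "F"), ("TRA", "F")),
    9: (("TRA", "F"), ("TRA", "N")),
    10: (("TRA", "N"), ("TRA", "N")),
    11: (("TRB", "F"), ("TRA", "F")),
    12: (("TRB", "F"), ("TRA", "N")),
    13: (("TRB", "N"), ("TRA", "F")),
    14: (("TRB", "N"), ("TRA", "N")),
    15: (("TRB", "F"),) * 3,
    16: (("TRB", "F"), ("TRB", "F"), ("TRB", "N")),
    17: (("TRB", "F"), ("TRB", "N"), ("TRB", "N")),
    18: (("TRB", "N"),) * 3,
    19: (("TRA", "F"),) * 3,
    20: (("TRA", "F"), ("TRA", "F"), ("TRA", "N")),
    21: (("TRA", "F"), ("TRA", "N"), ("TRA", "N")),
    22: (("TRA", "N"),) * 3,
}

#: concrete mixed multisets realizing category 23 "others"
_OTHERS_CHOICES: tuple[tuple[tuple[str, str], ...], ...] = (
    (("TRB", "F"), ("TRB", "F"), ("TRA", "F")),
    (("TRB", "F"), ("TRA", "F"), ("TRA", "F")),
    (("TRB", "F"), ("TRA", "F"), ("TRA", "N")),
    (("TRB", "F"), ("TRB", "N"), ("TRA", "F")),
    (("TRB", "N"), ("TRA", "F"), ("TRA", "N")),
    (("TRB", "F"), ("TRB", "F"), ("TRA", "F"), ("TRA", "F")),
    (("TRB", "F"), ("TRB", "N"), ("TRA", "F"), ("TRA", "N")),
)


def _realize_pattern(rng: np.random.Generator, code: int) -> tuple[tuple[str, str], ...]:
    if code == 23:
        return _OTHERS_CHOICES[int(rng.integers(len(_OTHERS_CHOICES)))]
    return _PATTERN_MULTISETS[code]


# ---------------------------------------------------------------------------
# planted mechanism cells
# ---------------------------------------------------------------------------

def _plant_events(rng: np.random.Generator, mechanism: str,
                  maps: dict[str, LocusMap]) -> list[tuple[ChainAnnotation, bool]]:
    """Draw a mechanism-feasible same-locus chain pair (+ a partner chain).

    The drawn gene combination is re-verified against the excision oracle;
    generation retries until it passes (by construction it always should).
    """
    for _ in range(100):
        if mechanism == "trec_circle_beta":
            lm = maps["TRB"]
            vs = sorted(lm.segments("V", functionality="F"),
                        key=lambda g: g.ordinal)
            fwd = [v for v in vs if v.orientation == "forward"]
            i_b = int(rng.integers(len(fwd) - 1))
            v_b = fwd[i_b]
            v_a = _choice(rng, fwd[i_b + 1:])
            a = _beta_chain(rng, lm, v_a, "DJC1")
            b = _beta_chain(rng, lm, v_b, "DJC2")
            circle, chrom = a, b
        elif mechanism == "inversion_v30":
            lm = maps["TRB"]
            rev = lm.reverse_v
            fwd = [v for v in lm.segments("V", functionality="F")
                   if v.orientation == "forward"]
            a = _beta_chain(rng, lm, rev, "DJC2")
            b = _beta_chain(rng, lm, _choice(rng, fwd), "DJC1")
            circle, chrom = a, b
        else:  # trec_circle_alpha
            lm = maps["TRA"]
            vs = sorted(lm.segments("V", functionality="F"),
                        key=lambda g: g.ordinal)
            js = sorted(lm.segments("J", functionality="F"),
                        key=lambda g: g.ordinal)
            i_vb = int(rng.integers(len(vs) - 1))
            i_jb = int(rng.integers(1, len(js)))
            v_b, j_b = vs[i_vb], js[i_jb]
            v_a = _choice(rng, vs[i_vb + 1:])
            j_a = _choice(rng, js[:i_jb])
            a = _alpha_chain(rng, lm, v_a, j_a)
            b = _alpha_chain(rng, lm, v_b, j_b)
            circle, chrom = a, b
        ev_circle = event_from_chain(circle, lm)
        ev_chrom = event_from_chain(chrom, lm)
        if brute_force_excision_oracle([ev_circle, ev_chrom], lm, [[0, 1]]):
            break
    else:  # pragma: no cover - construction guarantees feasibility
        raise RuntimeError(f"could not plant mechanism {mechanism}")
    # partner chain on the other locus so planted cells carry >=3 chains
    other = "TRA" if circle.locus == "TRB" else "TRB"
    partner, _ = _draw_chain(rng, other, "F", maps)
    return [(circle, True), (chrom, True), (partner, True)]


def _beta_chain(rng, lm: LocusMap, v, cluster: str) -> ChainAnnotation:
    d = lm.segments("D", cluster=cluster)[0]
    j = _choice(rng, lm.segments("J", cluster=cluster, functionality="F"))
    c = lm.segments("C", cluster=cluster)[0]
    return ChainAnnotation("TRB", v.name, d.name, j.name, c.name,
                           _junction(rng), "F" if v.functionality == "F" else "N")


def _alpha_chain(rng, lm: LocusMap, v, j) -> ChainAnnotation:
    return ChainAnnotation("TRA", v.name, "", j.name, "TRAC",
                           _junction(rng), "F" if v.functionality == "F" else "N")


# ---------------------------------------------------------------------------
# sample generation
# ---------------------------------------------------------------------------

def _contig_row(chain: ChainAnnotation, productive: bool, barcode: str,
                contig_id: str, umis: int) -> dict:
    return {
        "barcode": barcode,
        "is_cell": "True",
        "high_confidence": "True",
        "chain": chain.locus,
        "v_gene": chain.v_call,
        "d_gene": chain.d_call,
        "j_gene": chain.j_call,
        "c_gene": chain.c_call,
        "cdr3": chain.junction_aa,
        "productive": "True" if productive else "False",
        "umis": umis,
        "contig_id": contig_id,
    }


def generate_sample(
    config: SynthConfig,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one sample; returns (contig table, truth table).

    The truth table has one row per generated cell: barcode, true pattern
    code, true status, planted mechanism (or ``none``) and the chain list.
    When ``out_path`` is given the contig table is also written in the
    configured dialect.
    """
    rng = np.random.default_rng(config.seed)
    maps = {locus: load_locus(config.species, locus) for locus in ("TRA", "TRB")}
    weights = np.asarray(config.pattern_weights, dtype=float)
    weights = weights / weights.sum()

    n_planted = {m: int(round(r * config.n_cells))
                 for m, r in config.mechanism_plant_rates.items()}
    if sum(n_planted.values()) > config.n_cells:
        raise ValueError("mechanism plant rates exceed the cell budget")

    plant_assignment: list[str | None] = []
    for m, k in n_planted.items():
        plant_assignment.extend([m] * k)
    plant_assignment.extend([None] * (config.n_cells - len(plant_assignment)))
    order = rng.permutation(config.n_cells)
    plant_assignment = [plant_assignment[k] for k in order]

    contig_rows: list[dict] = []
    truth_rows: list[dict] = []
    codes = rng.choice(np.arange(1, 24), size=config.n_cells, p=weights)
    for i in range(config.n_cells):
        barcode = f"CELL{i:06d}-1"
        mechanism = plant_assignment[i]
        if mechanism is not None:
            chain_pairs = _plant_events(rng, mechanism, maps)
        else:
            multiset = _realize_pattern(rng, int(codes[i]))
            chain_pairs = []
            seen: set[tuple] = set()
            for locus, status in multiset:
                for _ in range(50):
                    chain, productive = _draw_chain(rng, locus, status, maps)
                    if chain.identity_key not in seen:
                        seen.add(chain.identity_key)
                        break
                chain_pairs.append((chain, productive))
        profile = CellProfile(barcode=barcode,
                              chains=tuple(sorted(c for c, _ in chain_pairs)))
        label = cell_patterns.assign_pattern(profile)
        truth_rows.append({
            "barcode": barcode,
            "pattern_code": label.code,
            "tcr_status": cell_patterns.classify_tcr_status(profile),
            "chain_count_group": cell_patterns.chain_count_group(profile),
            "planted_mechanism": mechanism or "none",
            "chains": ";".join("|".join(c.identity_key) for c, _ in chain_pairs),
        })
        for j, (chain, productive) in enumerate(chain_pairs):
            contig_rows.append(_contig_row(
                chain, productive, barcode,
                contig_id=f"{barcode}_contig_{j}",
                umis=int(rng.integers(1, 100)),
            ))

    _append_noise(rng, contig_rows, config)

    contigs = pd.DataFrame(contig_rows, columns=[
        "barcode", "is_cell", "high_confidence", "chain", "v_gene", "d_gene",
        "j_gene", "c_gene", "cdr3", "productive", "umis", "contig_id",
    ])
    truth = pd.DataFrame(truth_rows, columns=[
        "barcode", "pattern_code", "tcr_status", "chain_count_group",
        "planted_mechanism", "chains",
    ])
    if out_path is not None:
        write_contig_table(contigs, out_path, config.dialect)
    return contigs, truth


def _append_noise(rng: np.random.Generator, rows: list[dict],
                  config: SynthConfig) -> None:
    """Inject QC-failing rows, reusing existing barcodes where possible."""
    maps = {locus: load_locus(config.species, locus) for locus in ("TRA", "TRB")}
    barcodes = [r["barcode"] for r in rows] or ["NOISE000000-1"]
    k = len(rows)
    for reason, proportion in config.qc_noise.items():
        count = int(round(proportion * config.n_cells))
        for _ in range(count):
            chain, productive = _draw_chain(rng, "TRB" if rng.random() < 0.5
                                            else "TRA", "F", maps)
            row = _contig_row(chain, productive,
                              barcode=barcodes[int(rng.integers(len(barcodes)))],
                              contig_id=f"noise_{reason}_{k}",
                              umis=int(rng.integers(1, 100)))
            k += 1
            if reason == "not_cell":
                row["is_cell"] = "FALSE"
            elif reason == "low_confidence":
                row["high_confidence"] = "FALSE"
            elif reason == "wrong_chain":
                row["chain"] = "IGH" if rng.random() < 0.5 else "Multi"
            elif reason == "productive_none":
                row["productive"] = "None"
            rows.append(row)


def write_contig_table(contigs: pd.DataFrame, path: str | Path,
                       dialect: str) -> None:
    path = Path(path)
    if dialect == "tenx_csv":
        contigs.to_csv(path, index=False)
    elif dialect == "airr_tsv":
        airr = pd.DataFrame({
            "cell_id": contigs["barcode"],
            "sequence_id": contigs["contig_id"],
            "locus": contigs["chain"],
            "v_call": contigs["v_gene"],
            "d_call": contigs["d_gene"],
            "j_call": contigs["j_gene"],
            "c_call": contigs["c_gene"],
            "junction_aa": contigs["cdr3"],
            "productive": contigs["productive"],
            "duplicate_count": contigs["umis"],
            "is_cell": contigs["is_cell"],
            "high_confidence": contigs["high_confidence"],
        })
        airr.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sequential rearrangement process
# ---------------------------------------------------------------------------

def simulate_rearrangement_process(
    n_cells: int,
    p_productive: float,
    seed: int,
) -> pd.DataFrame:
    """Sequential biallelic rearrangement attempts per cell.

    Each cell attempts a rearrangement on the first allele; with
    probability ``p_productive`` it is productive and the cell stops
    (allelic exclusion).  Otherwise the second allele attempts once more.
    With p = 1/3, a fraction 1/3 of cells succeed on the first attempt and
    (1 - 1/3) x 1/3 = 2/9 on the second.
    """
    if not 0 < p_productive <= 1:
        raise ValueError("p_productive must be in (0, 1]")
    rng = np.random.default_rng(seed)
    first = rng.random(n_cells) < p_productive
    second_attempted = ~first
    second = second_attempted & (rng.random(n_cells) < p_productive)
    return pd.DataFrame({
        "attempts": np.where(first, 1, 2),
        "productive_first": first,
        "productive_second": second,
        "productive": first | second,
    })
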