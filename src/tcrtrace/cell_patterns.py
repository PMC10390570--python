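"""Per-cell chain-pattern, chain-count-group, and TCR-status classification.

Each cell's multiset of distinct chains, reduced to counts of
(locus, functional-status) — beta(F), beta(N), alpha(F), alpha(N) — maps to
one of 23 pattern categories:

* 1-4: single-chain cells,
* 5-14: all two-chain combinations,
* 15-22: the same-locus three-chain combinations,
* 23 "others": everything else (mixed three-chain combinations and all
  cells with four or more chains).

Independently of the pattern, cells are grouped by number of distinct
chains (one / two / three-plus) and assigned a TCR status from alpha/beta
pairing:

* ``single``   — exactly one beta(F) and one alpha(F), any number of N chains;
* ``multiple`` — at least one of each and three or more F chains in total
  (more than one way to assemble a functional alpha-beta pair);
* ``abnormal`` — no beta(F)+alpha(F) pair at all.

A *functional cell* is one whose status is single or multiple.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chain_model import CellProfile

#: Canonical pattern names, keyed by code.  B=TCR beta, A=TCR alpha.
PATTERN_NAMES: dict[int, str] = {
    1: "TRB(F)",
    2: "TRB(N)",
    3: "TRA(F)",
    4: "TRA(N)",
    5: "TRB(F)+TRB(F)",
    6: "TRB(F)+TRB(N)",
    7: "TRB(N)+TRB(N)",
    8: "TRA(F)+TRA(F)",
    9: "TRA(F)+TRA(N)",
    10: "TRA(N)+TRA(N)",
    11: "TRB(F)+TRA(F)",
    12: "TRB(F)+TRA(N)",
    13: "TRB(N)+TRA(F)",
    14: "TRB(N)+TRA(N)",
    15: "TRB(F)+TRB(F)+TRB(F)",
    16: "TRB(F)+TRB(F)+TRB(N)",
    17: "TRB(F)+TRB(N)+TRB(N)",
    18: "TRB(N)+TRB(N)+TRB(N)",
    19: "TRA(F)+TRA(F)+TRA(F)",
    20: "TRA(F)+TRA(F)+TRA(N)",
    21: "TRA(F)+TRA(N)+TRA(N)",
    22: "TRA(N)+TRA(N)+TRA(N)",
    23: "others",
}

#: (n_trb_f, n_trb_n, n_tra_f, n_tra_n) signature -> pattern code 1-22.
_SIGNATURES: dict[tuple[int, int, int, int], int] = {
    (1, 0, 0, 0): 1,
    (0, 1, 0, 0): 2,
    (0, 0, 1, 0): 3,
    (0, 0, 0, 1): 4,
    (2, 0, 0, 0): 5,
    (1, 1, 0, 0): 6,
    (0, 2, 0, 0): 7,
    (0, 0, 2, 0): 8,
    (0, 0, 1, 1): 9,
    (0, 0, 0, 2): 10,
    (1, 0, 1, 0): 11,
    (1, 0, 0, 1): 12,
    (0, 1, 1, 0): 13,
    (0, 1, 0, 1): 14,
    (3, 0, 0, 0): 15,
    (2, 1, 0, 0): 16,
    (1, 2, 0, 0): 17,
    (0, 3, 0, 0): 18,
    (0, 0, 3, 0): 19,
    (0, 0, 2, 1): 20,
    (0, 0, 1, 2): 21,
    (0, 0, 0, 3): 22,
}

STATUSES = ("single", "multiple", "abnormal")
GROUPS = ("one", "two", "three_plus")


@dataclass(frozen=True)
class PatternLabel:
    code: int
    name: str


def _signature(profile: CellProfile) -> tuple[int, int, int, int]:
    return (profile.n_trb_f, profile.n_trb_n, profile.n_tra_f, profile.n_tra_n)


def assign_pattern(profile: CellProfile) -> PatternLabel:
    """Map a cell to its pattern category (1-23).

    Determined solely by the multiset of (locus, status) over the cell's
    distinct chains; anything not in the explicit 22-entry list falls to
    category 23 "others".
    """
    _require_chains(profile)
    code = _SIGNATURES.get(_signature(profile), 23)
    return PatternLabel(code=code, name=PATTERN_NAMES[code])


def chain_count_group(profile: CellProfile) -> str:
    """'one' / 'two' / 'three_plus' by the number of distinct chains."""
    _require_chains(profile)
    n = profile.n_chains
    return "one" if n == 1 else "two" if n == 2 else "three_plus"


def classify_tcr_status(profile: CellProfile) -> str:
    """'single' / 'multiple' / 'abnormal' from alpha/beta(F) pairing."""
    _require_chains(profile)
    b, a = profile.n_trb_f, profile.n_tra_f
    if b == 0 or a == 0:
        return "abnormal"
    if b == 1 and a == 1:
        return "single"
    return "multiple"


def is_functional_cell(profile: CellProfile) -> bool:
    """True iff the cell can assemble at least one functional alpha-beta TCR."""
    _require_chains(profile)
    return profile.n_trb_f >= 1 and profile.n_tra_f >= 1


def _require_chains(profile: CellProfile) -> None:
    if profile.n_chains == 0:
        raise ValueError(f"cell {profile.barcode} has no chains to classify")


def classification_table(profiles: list[CellProfile]) -> pd.DataFrame:
    """Per-cell classification table (one row per cell)."""
    rows = []
    for p in profiles:
        label = assign_pattern(p)
        rows.append({
            "barcode": p.barcode,
            "pattern_code": label.code,
            "pattern_name": label.name,
            "chain_count_group": chain_count_group(p),
            "tcr_status": classify_tcr_status(p),
            "n_tra_f": p.n_tra_f,
            "n_tra_n": p.n_tra_n,
            "n_trb_f": p.n_trb_f,
            "n_trb_n": p.n_trb_n,
        })
    return pd.DataFrame(rows)


def write_classification_table(profiles: list[CellProfile], path: str | Path) -> None:
    classification_table(profiles).to_csv(path, sep="\t", index=False)
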