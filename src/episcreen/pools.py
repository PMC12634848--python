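"""Two-dimensional matrix pooling and deconvolution.

The 50-candidate panel of each allele is laid out row-major by rank in a
7 x 7 grid.  Each row is one "horizontal" pool (ids 1-7) and each column one
"vertical" pool (ids 8-14), so every peptide is stimulated in exactly two of
the 14 pools.  After pool-level screening, a candidate is nominated when
both of its pools respond (the cross-product decode); non-responding pools
are crossed out.  With 50 candidates in 49 cells the lowest-ranked candidate
shares the last cell and is flagged ambiguous, to be resolved at the
single-peptide stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .ranking import PeptideCandidate


class CapacityError(ValueError):
    """The panel does not fit the grid plus overflow allowance."""


@dataclass(frozen=True)
class PoolDesign:
    """A matrix pooling layout for one allele.

    grid maps (row, col), both 1-based, to the candidate ids in that cell;
    pool ids 1..n_rows are horizontal (rows), n_rows+1..n_rows+n_cols
    vertical (columns).  candidate_order lists ids by rank_index and fixes
    decode output order.
    """

    allele: str
    n_rows: int = 7
    n_cols: int = 7
    grid: Mapping[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)
    candidate_order: tuple[str, ...] = ()

    @property
    def horizontal_pools(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_rows + 1))

    @property
    def vertical_pools(self) -> tuple[int, ...]:
        return tuple(range(self.n_rows + 1, self.n_rows + self.n_cols + 1))

    @property
    def pool_ids(self) -> tuple[int, ...]:
        return self.horizontal_pools + self.vertical_pools

    @property
    def pool_membership(self) -> dict[int, frozenset[str]]:
        """Derived pool -> candidate-id sets (each candidate in exactly two)."""
        members: dict[int, set[str]] = {pid: set() for pid in self.pool_ids}
        for (row, col), ids in self.grid.items():
            members[row].update(ids)
            members[self.n_rows + col].update(ids)
        return {pid: frozenset(ids) for pid, ids in members.items()}

    @property
    def shared_cell_ids(self) -> frozenset[str]:
        """Candidates co-located in a multiply-occupied cell."""
        shared: set[str] = set()
        for ids in self.grid.values():
            if len(ids) > 1:
                shared.update(ids)
        return frozenset(shared)

    def pools_of(self, candidate_id: str) -> tuple[int, int]:
        """(horizontal, vertical) pool ids of one candidate."""
        for (row, col), ids in self.grid.items():
            if candidate_id in ids:
                return (row, self.n_rows + col)
        raise KeyError(candidate_id)


@dataclass(frozen=True)
class DeconvolutionResult:
    """Outcome of crossing positive pools: nominated candidates, rank order."""

    allele: str
    positive_horizontal: frozenset[int]
    positive_vertical: frozenset[int]
    candidates: tuple[str, ...]
    ambiguous: frozenset[str]


def build_matrix(
    panel: Sequence[PeptideCandidate],
    n_rows: int = 7,
    n_cols: int = 7,
    overflow_allowance: int = 1,
) -> PoolDesign:
    """Place panel candidates row-major by rank into the pooling grid.

    Candidate i (1-based rank) occupies cell (ceil(i/n_cols), ((i-1) mod
    n_cols)+1); candidates beyond n_rows*n_cols share the last cell, up to
    `overflow_allowance` extra occupants.
    """
    if not panel:
        raise ValueError("empty panel")
    capacity = n_rows * n_cols
    if len(panel) > capacity + overflow_allowance:
        raise CapacityError(
            f"panel of {len(panel)} exceeds {n_rows}x{n_cols} grid plus "
            f"overflow allowance {overflow_allowance}"
        )
    ordered = sorted(panel, key=lambda c: c.rank_index)
    grid: dict[tuple[int, int], list[str]] = {}
    for i, candidate in enumerate(ordered, start=1):
        if i <= capacity:
            cell = ((i - 1) // n_cols + 1, (i - 1) % n_cols + 1)
        else:
            cell = (n_rows, n_cols)
        grid.setdefault(cell, []).append(candidate.candidate_id)
    return PoolDesign(
        allele=ordered[0].allele,
        n_rows=n_rows,
        n_cols=n_cols,
        grid={cell: tuple(ids) for cell, ids in grid.items()},
        candidate_order=tuple(c.candidate_id for c in ordered),
    )


def pool_manifest(design: PoolDesign) -> pd.DataFrame:
    """One row per (pool_id, candidate_id); 2 rows per candidate."""
    rows = [
        {"allele": design.allele, "pool_id": pid, "candidate_id": cid}
        for pid in design.pool_ids
        for cid in sorted(design.pool_membership[pid], key=design.candidate_order.index)
    ]
    return pd.DataFrame(rows, columns=["allele", "pool_id", "candidate_id"])


def membership_from_manifest(manifest: pd.DataFrame) -> dict[int, frozenset[str]]:
    """Rebuild pool membership from a manifest table (round-trip check)."""
    members: dict[int, set[str]] = {}
    for _, row in manifest.iterrows():
        members.setdefault(int(row["pool_id"]), set()).add(str(row["candidate_id"]))
    return {pid: frozenset(ids) for pid, ids in members.items()}


def decode(design: PoolDesign, positive_pools: Iterable[int]) -> DeconvolutionResult:
    """Cross out non-positive pools; nominate candidates with both pools positive.

    Candidates sharing a multiply-occupied cell are flagged ambiguous (their
    nomination cannot be attributed within the pool data alone).  Output is
    ordered by rank.
    """
    positive = set(positive_pools)
    unknown = positive - set(design.pool_ids)
    if unknown:
        raise ValueError(f"unknown pool ids: {sorted(unknown)}")
    horizontal = frozenset(p for p in positive if p in design.horizontal_pools)
    vertical = frozenset(p for p in positive if p in design.vertical_pools)
    nominated: list[str] = []
    ambiguous: set[str] = set()
    shared = design.shared_cell_ids
    for cid in design.candidate_order:
        row_pool, col_pool = design.pools_of(cid)
        if row_pool in horizontal and col_pool in vertical:
            nominated.append(cid)
            if cid in shared:
                ambiguous.add(cid)
    return DeconvolutionResult(
        allele=design.allele,
        positive_horizontal=horizontal,
        positive_vertical=vertical,
        candidates=tuple(nominated),
        ambiguous=frozenset(ambiguous),
    )


def design_to_yaml(design: PoolDesign, path: str | Path) -> None:
    """Serialise a design (allele, dims, grid, candidate order) to YAML."""
    payload = {
        "allele": design.allele,
        "n_rows": design.n_rows,
        "n_cols": design.n_cols,
        "orientation": "pools 1..n_rows horizontal, rest vertical",
        "grid": {f"{r},{c}": list(ids) for (r, c), ids in sorted(design.grid.items())},
        "candidate_order": list(design.candidate_order),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def design_from_yaml(path: str | Path) -> PoolDesign:
    payload = yaml.safe_load(Path(path).read_text())
    grid = {
        tuple(int(x) for x in key.split(",")): tuple(ids)
        for key, ids in payload["grid"].items()
    }
    return PoolDesign(
        allele=payload["allele"],
        n_rows=int(payload["n_rows"]),
        n_cols=int(payload["n_cols"]),
        grid=grid,
        candidate_order=tuple(payload["candidate_order"]),
    )
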