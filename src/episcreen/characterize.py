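"""Characterization of confirmed epitopes.

Once the two-stage screen has confirmed epitopes, this module summarises
them the way an epitope-mapping study reports its catalogue: distribution
over the viral proteins (the gene-position gradient makes upstream proteins
the expected hot spots), length histogram per allele, anchor-residue motif
conformity, nested same-allele pairs (length variants sharing a core), exact
sequence sharing across mouse strains, and eligibility for commercial pMHC
multimer synthesis (predicted affinity at or below 1,000 nM).

Motif conformity is descriptive only — it never filters confirmation, since
low-affinity binders can still be immunogenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .motifs import AnchorMotif, DEFAULT_MOTIFS, motif_for  # noqa: F401  (re-export)
from .proteome import GENOME_ORDER
from .ranking import ScoreBundle

#: Manufacturer cutoff for pMHC multimer production (predicted IC50, nM).
MULTIMER_AFFINITY_CUTOFF_NM = 1000.0


@dataclass(frozen=True)
class EpitopeRecord:
    """A confirmed epitope with its validation flags and characterization."""

    allele: str
    candidate_id: str
    sequence: str
    protein: str
    start: int
    elispot_confirmed: bool = False
    ics_confirmed: bool = False
    multimer_confirmed: bool = False
    scores: ScoreBundle | None = None

    def __post_init__(self) -> None:
        if not 8 <= len(self.sequence) <= 11:
            raise ValueError("epitope length must be 8-11")

    @property
    def length(self) -> int:
        return len(self.sequence)


def protein_distribution(epitopes: Sequence[EpitopeRecord]) -> pd.DataFrame:
    """Epitope counts and percentages per protein, across all alleles."""
    counts = {p: 0 for p in GENOME_ORDER}
    for e in epitopes:
        counts[e.protein] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "protein": list(GENOME_ORDER),
            "count": [counts[p] for p in GENOME_ORDER],
            "percent": [
                100.0 * counts[p] / total if total else 0.0 for p in GENOME_ORDER
            ],
        }
    )


def length_distribution(epitopes: Sequence[EpitopeRecord]) -> pd.DataFrame:
    """Per-(allele, length) histogram over lengths 8-11 plus global min/max.

    Only (allele, length) combinations for alleles present are emitted; the
    frame carries `min_length`/`max_length` attrs (None when empty).
    """
    rows = []
    alleles = sorted({e.allele for e in epitopes})
    for allele in alleles:
        for length in range(8, 12):
            n = sum(1 for e in epitopes if e.allele == allele and e.length == length)
            rows.append({"allele": allele, "length": length, "count": n})
    frame = pd.DataFrame(rows, columns=["allele", "length", "count"])
    lengths = [e.length for e in epitopes]
    frame.attrs["min_length"] = min(lengths) if lengths else None
    frame.attrs["max_length"] = max(lengths) if lengths else None
    return frame


def anchor_report(
    epitope: EpitopeRecord | str, motif: AnchorMotif
) -> dict[str, bool | str]:
    """Per-rule anchor match flags plus overall conformity.

    Accepts a record or a bare sequence.  An empty motif is vacuously
    conformant.
    """
    sequence = epitope if isinstance(epitope, str) else epitope.sequence
    rule_positions = [p for p in motif.position_rules]
    if rule_positions and len(sequence) < max(rule_positions):
        raise ValueError("epitope shorter than the highest anchor position")
    flags = motif.match(sequence)
    return {"sequence": sequence, **flags, "conformant": all(flags.values())}


@dataclass(frozen=True)
class NestedPair:
    shorter: str
    longer: str
    length_difference: int
    allele: str | None = None  # None marks a cross-allele pair


def nested_pairs(
    epitopes: Sequence[EpitopeRecord],
) -> tuple[list[NestedPair], list[NestedPair]]:
    """Length-variant pairs where the shorter sequence is a substring of the longer.

    Returns (within_allele, cross_allele); each unordered pair is reported
    once, regardless of input order.
    """
    within: list[NestedPair] = []
    cross: list[NestedPair] = []
    seen: set[tuple[str, str]] = set()
    records = sorted(epitopes, key=lambda e: (e.allele, e.candidate_id))
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            short, long_ = sorted((a.sequence, b.sequence), key=len)
            if short == long_ or short not in long_:
                continue
            key = (short, long_)
            pair = NestedPair(
                shorter=short,
                longer=long_,
                length_difference=len(long_) - len(short),
                allele=a.allele if a.allele == b.allele else None,
            )
            if a.allele == b.allele:
                if (a.allele,) + key not in seen:
                    within.append(pair)
                    seen.add((a.allele,) + key)
            else:
                if ("x",) + key not in seen:
                    cross.append(pair)
                    seen.add(("x",) + key)
    return within, cross


def shared_across_sets(
    set_a: Iterable[str], set_b: Iterable[str]
) -> list[str]:
    """Exact, case-normalised sequence intersection between two epitope sets."""
    a = {s.upper() for s in set_a}
    b = {s.upper() for s in set_b}
    return sorted(a & b)


def multimer_eligibility(
    epitope: EpitopeRecord, affinity_cutoff_nM: float = MULTIMER_AFFINITY_CUTOFF_NM
) -> bool | None:
    """Whether the predicted affinity permits multimer synthesis.

    Eligible iff affinity <= cutoff (a value exactly at the cutoff counts as
    eligible; "above" is the exclusion).  Returns None when the affinity is
    unavailable (indeterminate).
    """
    if epitope.scores is None:
        return None
    return epitope.scores.affinity_nM <= affinity_cutoff_nM


def epitopes_to_frame(epitopes: Sequence[EpitopeRecord]) -> pd.DataFrame:
    """Tabular epitope report."""
    return pd.DataFrame(
        [
            {
                "allele": e.allele,
                "candidate_id": e.candidate_id,
                "sequence": e.sequence,
                "protein": e.protein,
                "start": e.start,
                "length": e.length,
                "elispot_confirmed": e.elispot_confirmed,
                "ics_confirmed": e.ics_confirmed,
                "multimer_confirmed": e.multimer_confirmed,
                "affinity_nM": e.scores.affinity_nM if e.scores else None,
                "percent_rank": e.scores.percent_rank if e.scores else None,
                "multimer_eligible": multimer_eligibility(e),
            }
            for e in epitopes
        ]
    )


def characterization_summary(epitopes: Sequence[EpitopeRecord]) -> dict:
    """Structured summary: protein distribution, length histogram, nesting."""
    proteins = protein_distribution(epitopes)
    lengths = length_distribution(epitopes)
    within, cross = nested_pairs(epitopes)
    return {
        "n_epitopes": len(epitopes),
        "protein_counts": dict(zip(proteins["protein"], proteins["count"])),
        "protein_percent": {
            p: round(v, 2) for p, v in zip(proteins["protein"], proteins["percent"])
        },
        "length_min": lengths.attrs["min_length"],
        "length_max": lengths.attrs["max_length"],
        "length_counts": {
            f"{row.allele}:{row.length}": int(row.count)
            for row in lengths.itertuples()
            if row.count
        },
        "nested_within_allele": [
            {"shorter": p.shorter, "longer": p.longer, "diff": p.length_difference}
            for p in within
        ],
        "nested_cross_allele": [
            {"shorter": p.shorter, "longer": p.longer, "diff": p.length_difference}
            for p in cross
        ],
    }
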