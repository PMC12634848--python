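"""Predictor-score handling, binder tiering, and gradient panel selection.

Binding/stability predictors are run outside the package; their tabular
exports are ingested by :func:`load_scores`.  For fully self-contained runs
(and tests), :func:`surrogate_score` provides a deterministic anchor-motif
scorer with the same output shape.

Panel selection reproduces the campaign's gene-position gradient: the 50
best-ranked candidates per allele are drawn per protein under a decreasing
quota (default 15/15/10/5/5 for N/P/M/GP/L), mirroring the protein-abundance
gradient of sequential rhabdovirus transcription.  Candidate identifiers are
the protein letter plus the global panel index (N1-N15, P16-P30, M31-M40,
G41-G45, L46-L50).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .motifs import motif_for
from .proteome import GENOME_ORDER, PROTEIN_LETTER, PeptideWindow

#: Default percent-rank tier thresholds; a boundary value takes the weaker tier.
TIER_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("strong", 0.5),
    ("weak", 2.0),
    ("marginal", 10.0),
)

#: Default per-protein quotas of the 50-candidate panel, in genome order.
DEFAULT_QUOTAS: Mapping[str, int] = {"N": 15, "P": 15, "M": 10, "GP": 5, "L": 5}


class ScoreTableError(ValueError):
    """A predictor score table is malformed."""


@dataclass(frozen=True)
class ScoreBundle:
    """Predictor outputs for one (peptide, allele) pair.

    affinity_nM is a predicted IC50 (lower = stronger binding); percent_rank
    is rank-normalised against random peptides (lower = stronger); stability
    and immunogenicity are optional, higher = better.
    """

    affinity_nM: float
    percent_rank: float
    stability: float | None = None
    immunogenicity: float | None = None

    def __post_init__(self) -> None:
        if not self.affinity_nM > 0:
            raise ScoreTableError(f"affinity must be positive, got {self.affinity_nM}")
        if self.percent_rank < 0:
            raise ScoreTableError(f"percent rank must be >= 0, got {self.percent_rank}")

    @property
    def tier(self) -> str:
        return tier_binders(self)


def tier_binders(
    bundle: ScoreBundle,
    thresholds: Sequence[tuple[str, float]] = TIER_THRESHOLDS,
) -> str:
    """Tier a binder from its percent rank: strong < 0.5 <= weak < 2.0 <= marginal < 10.0 <= non.

    Strict inequalities: a peptide exactly on a boundary falls in the weaker
    tier.  Lower percent rank never yields a weaker tier.
    """
    if bundle.percent_rank is None:  # defensive; dataclass requires it
        raise ScoreTableError("percent_rank missing")
    for name, cutoff in thresholds:
        if bundle.percent_rank < cutoff:
            return name
    return "non"


@dataclass(frozen=True)
class PeptideCandidate:
    """One panel member: an allele-namespaced window with scores and rank.

    candidate_id is unique within an allele only; e.g. "P25" names different
    sequences in the H2-Kd and H2-Dd panels.
    """

    allele: str
    candidate_id: str
    window: PeptideWindow
    scores: ScoreBundle
    rank_index: int  # 1..budget, id order

    @property
    def sequence(self) -> str:
        return self.window.sequence


@dataclass(frozen=True)
class AllocationScheme:
    """Per-protein candidate quotas; must be non-increasing in genome order."""

    quotas: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_QUOTAS))

    def __post_init__(self) -> None:
        ordered = [self.quotas.get(p, 0) for p in GENOME_ORDER]
        if any(q < 0 for q in ordered):
            raise ValueError("quotas must be non-negative")
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("quotas must be non-increasing in genome order")

    @property
    def budget(self) -> int:
        return sum(self.quotas.get(p, 0) for p in GENOME_ORDER)


def _residual(allele: str, sequence: str) -> float:
    """Deterministic pseudo-noise in [0, 1) from a stable hash."""
    digest = hashlib.blake2b(f"{allele}|{sequence}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def surrogate_score(window: PeptideWindow, allele: str) -> ScoreBundle:
    """Deterministic anchor-motif scorer standing in for external predictors.

    The percent rank decreases with the number of allele anchor rules matched
    (strictly: the per-match step exceeds the residual spread), carries a mild
    penalty away from the canonical 9-mer length, and a hash-based residual
    that separates peptides with equal motif content.  Affinity, stability and
    immunogenicity are monotone transforms of the same rank.
    """
    motif = motif_for(allele)
    seq = window.sequence
    frac = motif.n_matched(seq) / motif.n_rules
    percent_rank = (
        24.0 * (1.0 - frac) + 0.6 * abs(window.length - 9) + 0.45 * _residual(allele, seq)
    )
    affinity = 2.0 * 10.0 ** (percent_rank / 7.0)
    stability = max(0.0, 6.0 - 0.2 * percent_rank)
    immunogenicity = 1.0 - percent_rank / 30.0
    return ScoreBundle(
        affinity_nM=affinity,
        percent_rank=percent_rank,
        stability=stability,
        immunogenicity=immunogenicity,
    )


def score_universe(
    windows: Sequence[PeptideWindow],
    allele: str,
    scorer: Callable[[PeptideWindow, str], ScoreBundle] = surrogate_score,
) -> dict[str, ScoreBundle]:
    """Score every distinct window sequence for one allele."""
    return {w.sequence: scorer(w, allele) for w in windows}


@dataclass(frozen=True)
class ScoreTable:
    """Parsed predictor export: bundles keyed by (allele, peptide) plus unscored windows."""

    bundles: Mapping[tuple[str, str], ScoreBundle]
    unscored: tuple[PeptideWindow, ...]

    def for_allele(self, allele: str) -> dict[str, ScoreBundle]:
        return {pep: b for (a, pep), b in self.bundles.items() if a == allele}


def load_scores(
    path: str | Path, universe: Sequence[PeptideWindow] | None = None
) -> ScoreTable:
    """Parse a tab-separated predictor score table.

    Required columns: peptide, allele, affinity_nM, percent_rank; optional:
    stability, immunogenicity.  Malformed or negative-affinity rows raise
    :class:`ScoreTableError` naming the offending line (1-based, header =
    line 1).  Universe windows without any row are returned as `unscored`.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["peptide", "allele", "affinity_nM", "percent_rank"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ScoreTableError(f"missing columns: {', '.join(missing)}")
    bundles: dict[tuple[str, str], ScoreBundle] = {}
    for idx, row in table.iterrows():
        line = int(idx) + 2  # header occupies line 1
        try:
            affinity = float(row["affinity_nM"])
            rank = float(row["percent_rank"])
            stability = (
                float(row["stability"])
                if "stability" in table.columns and pd.notna(row["stability"])
                else None
            )
            immuno = (
                float(row["immunogenicity"])
                if "immunogenicity" in table.columns and pd.notna(row["immunogenicity"])
                else None
            )
        except (TypeError, ValueError) as exc:
            raise ScoreTableError(f"malformed row at line {line}: {exc}") from None
        try:
            bundle = ScoreBundle(affinity, rank, stability, immuno)
        except ScoreTableError as exc:
            raise ScoreTableError(f"line {line}: {exc}") from None
        bundles[(str(row["allele"]), str(row["peptide"]).upper())] = bundle
    unscored: tuple[PeptideWindow, ...] = ()
    if universe is not None:
        scored_sequences = {pep for (_, pep) in bundles}
        unscored = tuple(w for w in universe if w.sequence not in scored_sequences)
    return ScoreTable(bundles=bundles, unscored=unscored)


def _composite_table(
    windows: Sequence[PeptideWindow], scores: Mapping[str, ScoreBundle]
) -> pd.DataFrame:
    """Scored windows with a composite rank (mean of available per-predictor ranks).

    Percent rank ascends (lower better); stability and immunogenicity descend.
    Duplicate sequences are kept once, attributed to the earliest
    (genome order, start) occurrence: one peptide is one stimulus.
    """
    rows = []
    for w in windows:
        bundle = scores.get(w.sequence)
        if bundle is None:
            continue
        rows.append(
            {
                "sequence": w.sequence,
                "protein": w.protein,
                "start": w.start,
                "length": w.length,
                "order": GENOME_ORDER.index(w.protein),
                "percent_rank": bundle.percent_rank,
                "stability": bundle.stability,
                "immunogenicity": bundle.immunogenicity,
                "affinity_nM": bundle.affinity_nM,
            }
        )
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["order", "start", "length"]).drop_duplicates(
        "sequence", keep="first"
    )
    ranks = [frame["percent_rank"].rank(method="average")]
    for col in ("stability", "immunogenicity"):
        if frame[col].notna().any():
            ranks.append(frame[col].rank(method="average", ascending=False))
    frame["composite"] = pd.concat(ranks, axis=1).mean(axis=1)
    return frame


def select_panel(
    windows: Sequence[PeptideWindow],
    scores: Mapping[str, ScoreBundle],
    allele: str,
    scheme: AllocationScheme | None = None,
) -> list[PeptideCandidate]:
    """Select the per-allele candidate panel under the gradient allocation.

    Per protein, the quota-best peptides by composite rank are taken; ties
    break on (affinity, genome order, start, sequence).  If a protein has
    fewer scored peptides than its quota the shortfall cascades to the next
    protein in genome order (with a warning).  Ids are assigned protein letter
    + global index in genome-then-rank order; rank_index follows id order.
    """
    scheme = scheme or AllocationScheme()
    frame = _composite_table(windows, scores)
    if frame.empty:
        if scheme.budget > 0 and windows:
            warnings.warn("no scored peptides; empty panel", stacklevel=2)
        return []
    frame = frame.sort_values(
        ["composite", "affinity_nM", "order", "start", "sequence"]
    ).reset_index(drop=True)

    selected_per_protein: dict[str, pd.DataFrame] = {}
    carry = 0
    for protein in GENOME_ORDER:
        want = scheme.quotas.get(protein, 0) + carry
        pool = frame[frame["protein"] == protein]
        take = pool.head(want)
        carry = want - len(take)
        if len(take) < scheme.quotas.get(protein, 0):
            warnings.warn(
                f"protein {protein}: only {len(take)} scored peptides for a quota of "
                f"{scheme.quotas.get(protein, 0)}; shortfall cascades forward",
                stacklevel=2,
            )
        selected_per_protein[protein] = take
    if carry > 0:
        warnings.warn(f"panel short by {carry} candidates", stacklevel=2)

    panel: list[PeptideCandidate] = []
    index = 0
    for protein in GENOME_ORDER:
        for _, row in selected_per_protein[protein].iterrows():
            index += 1
            bundle = scores[row["sequence"]]
            panel.append(
                PeptideCandidate(
                    allele=allele,
                    candidate_id=f"{PROTEIN_LETTER[protein]}{index}",
                    window=PeptideWindow(
                        sequence=row["sequence"],
                        protein=protein,
                        start=int(row["start"]),
                        length=int(row["length"]),
                    ),
                    scores=bundle,
                    rank_index=index,
                )
            )
    return panel


def panel_to_frame(panel: Sequence[PeptideCandidate]) -> pd.DataFrame:
    """Panel manifest (one row per candidate, rank order)."""
    return pd.DataFrame(
        [
            {
                "allele": c.allele,
                "candidate_id": c.candidate_id,
                "sequence": c.sequence,
                "protein": c.window.protein,
                "start": c.window.start,
                "length": c.window.length,
                "rank_index": c.rank_index,
                "tier": c.scores.tier,
                "percent_rank": c.scores.percent_rank,
                "affinity_nM": c.scores.affinity_nM,
                "stability": c.scores.stability,
                "immunogenicity": c.scores.immunogenicity,
            }
            for c in panel
        ]
    )


def write_panel(panel: Sequence[PeptideCandidate], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[PeptideCandidate]:
    """Re-read a panel manifest written by :func:`write_panel`."""
    frame = pd.read_csv(path, sep="\t")
    panel = []
    for _, row in frame.iterrows():
        bundle = ScoreBundle(
            affinity_nM=float(row["affinity_nM"]),
            percent_rank=float(row["percent_rank"]),
            stability=None if pd.isna(row["stability"]) else float(row["stability"]),
            immunogenicity=(
                None if pd.isna(row["immunogenicity"]) else float(row["immunogenicity"])
            ),
        )
        panel.append(
            PeptideCandidate(
                allele=str(row["allele"]),
                candidate_id=str(row["candidate_id"]),
                window=PeptideWindow(
                    sequence=str(row["sequence"]),
                    protein=str(row["protein"]),
                    start=int(row["start"]),
                    length=int(row["length"]),
                ),
                scores=bundle,
                rank_index=int(row["rank_index"]),
            )
        )
    return panel
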