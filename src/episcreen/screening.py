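"""ELISpot positivity calling and the two-stage pool/peptide screen.

A stimulus is called positive when an unpaired two-sample t test of treated
versus untreated spot counts is significant AND the treated mean reaches the
spot-count floor (default 60 spots per well, the acceptability line drawn in
the assay readout) AND the treated mean exceeds the control mean.  The floor
makes the screen conservative: background wells essentially never reach it,
so the effective type-I rate of pool calling is far below alpha.

Well tables are tidy DataFrames with columns (allele, mouse_id, group,
stimulus, spots); group is "control" or "treated"; stimulus is "NC", "PC",
"pool:<id>" or "peptide:<candidate_id>".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pools import DeconvolutionResult, PoolDesign, decode

WELL_COLUMNS = ("allele", "mouse_id", "group", "stimulus", "spots")


class WellTableError(ValueError):
    """A well table is malformed or incomplete."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the positivity call.

    alpha: significance level of the unpaired t test.
    floor: minimum treated mean spot count (the 60-spot line).
    background_ceiling: maximum acceptable NC mean in plate QC.
    welch: use Welch's t instead of Student's (equal-variance) t.
    multiplicity: "none" (per-pool raw tests, as in the original readout)
    or "bh" for Benjamini-Hochberg across the stimuli of one call set.
    saturated: counts flagged saturated ("TNTC") are excluded with a warning
    unless `saturation_value` is set, in which case they are capped there.
    """

    alpha: float = 0.05
    floor: float = 60.0
    background_ceiling: float = 50.0
    welch: bool = False
    multiplicity: str = "none"
    saturation_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.multiplicity not in ("none", "bh"):
            raise ValueError("multiplicity must be 'none' or 'bh'")


@dataclass(frozen=True)
class PositivityCall:
    """Statistical call for one stimulus."""

    stimulus: str
    mean_treated: float
    mean_control: float
    p_value: float
    passes_floor: bool
    positive: bool
    n_treated: int
    n_control: int
    indeterminate: bool = False


@dataclass(frozen=True)
class QCReport:
    """Plate-level control checks (PC above floor, NC below ceiling)."""

    passed: bool
    failures: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScreenResult:
    """Per-allele outcome of the two-stage screen."""

    allele: str
    pool_calls: tuple[PositivityCall, ...]
    positive_pools: frozenset[int]
    deconvolution: DeconvolutionResult
    peptide_calls: tuple[PositivityCall, ...]
    confirmed: tuple[str, ...]  # candidate ids, rank order


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise WellTableError(f"well table missing columns: {', '.join(missing)}")
    if (pd.to_numeric(wells["spots"], errors="coerce") < 0).any():
        raise WellTableError("negative spot counts")
    return wells


def _spots(wells: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Handle saturated counts; returns wells with numeric spots."""
    wells = wells.copy()
    saturated = wells["spots"].astype(str).str.upper().isin({"TNTC", "SAT"})
    if saturated.any():
        if config.saturation_value is None:
            warnings.warn(
                f"excluding {int(saturated.sum())} saturated well(s)", stacklevel=3
            )
            wells = wells[~saturated]
        else:
            wells.loc[saturated, "spots"] = config.saturation_value
    wells["spots"] = pd.to_numeric(wells["spots"])
    return wells


def qc_plate(wells: pd.DataFrame, config: ScreenConfig | None = None) -> QCReport:
    """Check positive/negative controls per group.

    Passes when, in every group present, the PC mean reaches the floor and
    the NC mean stays below the background ceiling.  Missing controls fail.
    """
    config = config or ScreenConfig()
    wells = _spots(_validate_wells(wells), config)
    failures: list[str] = []
    for group, sub in wells.groupby("group"):
        nc = sub.loc[sub["stimulus"] == "NC", "spots"]
        pc = sub.loc[sub["stimulus"] == "PC", "spots"]
        if nc.empty:
            failures.append(f"{group}: missing negative control")
        elif nc.mean() > config.background_ceiling:
            failures.append(
                f"{group}: negative control background {nc.mean():.1f} exceeds "
                f"ceiling {config.background_ceiling:g}"
            )
        if pc.empty:
            failures.append(f"{group}: missing positive control")
        elif pc.mean() < config.floor:
            failures.append(
                f"{group}: positive control below floor "
                f"({pc.mean():.1f} < {config.floor:g})"
            )
    return QCReport(passed=not failures, failures=tuple(failures))


def call_stimulus(
    wells: pd.DataFrame, config: ScreenConfig | None = None, stimulus: str | None = None
) -> PositivityCall:
    """Unpaired t test of treated vs control counts for one stimulus.

    Positive iff p < alpha AND treated mean >= floor AND treated mean >
    control mean.  A group with fewer than two wells yields an indeterminate
    (never positive) call.
    """
    config = config or ScreenConfig()
    wells = _spots(_validate_wells(wells), config)
    if stimulus is not None:
        wells = wells[wells["stimulus"] == stimulus]
    else:
        labels = wells["stimulus"].unique()
        if len(labels) > 1:
            raise WellTableError(f"wells span several stimuli: {sorted(labels)}")
        stimulus = labels[0] if len(labels) else "<none>"
    treated = wells.loc[wells["group"] == "treated", "spots"].to_numpy(float)
    control = wells.loc[wells["group"] == "control", "spots"].to_numpy(float)
    mean_t = float(treated.mean()) if treated.size else float("nan")
    mean_c = float(control.mean()) if control.size else float("nan")
    if treated.size < 2 or control.size < 2:
        return PositivityCall(
            stimulus=stimulus,
            mean_treated=mean_t,
            mean_control=mean_c,
            p_value=float("nan"),
            passes_floor=bool(treated.size and mean_t >= config.floor),
            positive=False,
            n_treated=int(treated.size),
            n_control=int(control.size),
            indeterminate=True,
        )
    with warnings.catch_warnings():
        # identical-valued groups trigger a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(treated, control, equal_var=not config.welch)
    p_value = float(result.pvalue)
    passes_floor = mean_t >= config.floor
    positive = (
        np.isfinite(p_value)
        and p_value < config.alpha
        and passes_floor
        and mean_t > mean_c
    )
    return PositivityCall(
        stimulus=stimulus,
        mean_treated=mean_t,
        mean_control=mean_c,
        p_value=p_value,
        passes_floor=passes_floor,
        positive=bool(positive),
        n_treated=int(treated.size),
        n_control=int(control.size),
    )


def _apply_bh(calls: list[PositivityCall], config: ScreenConfig) -> list[PositivityCall]:
    """Re-gate positivity on BH-adjusted p values (floor and direction unchanged)."""
    testable = [c for c in calls if not c.indeterminate and np.isfinite(c.p_value)]
    if not testable:
        return calls
    rejected, adjusted, _, _ = multipletests(
        [c.p_value for c in testable], alpha=config.alpha, method="fdr_bh"
    )
    adjusted_map = {
        c.stimulus: (float(p), bool(r))
        for c, p, r in zip(testable, adjusted, rejected)
    }
    out = []
    for call in calls:
        if call.stimulus in adjusted_map:
            p_adj, reject = adjusted_map[call.stimulus]
            out.append(
                PositivityCall(
                    stimulus=call.stimulus,
                    mean_treated=call.mean_treated,
                    mean_control=call.mean_control,
                    p_value=p_adj,
                    passes_floor=call.passes_floor,
                    positive=reject
                    and call.passes_floor
                    and call.mean_treated > call.mean_control,
                    n_treated=call.n_treated,
                    n_control=call.n_control,
                )
            )
        else:
            out.append(call)
    return out


def call_pools(
    wells: pd.DataFrame, design: PoolDesign, config: ScreenConfig | None = None
) -> tuple[list[PositivityCall], frozenset[int]]:
    """Call every pool of a design; returns calls and the positive pool set.

    A pool without wells is an indeterminate (never positive) call.
    """
    config = config or ScreenConfig()
    wells = _validate_wells(wells)
    calls: list[PositivityCall] = []
    for pid in design.pool_ids:
        stimulus = f"pool:{pid}"
        sub = wells[wells["stimulus"] == stimulus]
        if sub.empty:
            calls.append(
                PositivityCall(
                    stimulus=stimulus,
                    mean_treated=float("nan"),
                    mean_control=float("nan"),
                    p_value=float("nan"),
                    passes_floor=False,
                    positive=False,
                    n_treated=0,
                    n_control=0,
                    indeterminate=True,
                )
            )
        else:
            calls.append(call_stimulus(sub, config, stimulus=stimulus))
    if config.multiplicity == "bh":
        calls = _apply_bh(calls, config)
    positive = frozenset(
        int(c.stimulus.split(":", 1)[1]) for c in calls if c.positive
    )
    return calls, positive


def confirm_peptides(
    wells: pd.DataFrame,
    candidates: Sequence[str],
    config: ScreenConfig | None = None,
) -> tuple[list[PositivityCall], list[str]]:
    """Single-peptide confirmation stage: call each decoded candidate.

    Returns (calls, confirmed candidate ids in input order).  Candidates
    without wells are left unconfirmed with a warning.
    """
    config = config or ScreenConfig()
    wells = _validate_wells(wells)
    calls: list[PositivityCall] = []
    confirmed: list[str] = []
    for cid in candidates:
        stimulus = f"peptide:{cid}"
        sub = wells[wells["stimulus"] == stimulus]
        if sub.empty:
            warnings.warn(f"candidate {cid}: no wells; left unconfirmed", stacklevel=2)
            calls.append(
                PositivityCall(
                    stimulus=stimulus,
                    mean_treated=float("nan"),
                    mean_control=float("nan"),
                    p_value=float("nan"),
                    passes_floor=False,
                    positive=False,
                    n_treated=0,
                    n_control=0,
                    indeterminate=True,
                )
            )
            continue
        calls.append(call_stimulus(sub, config, stimulus=stimulus))
    if config.multiplicity == "bh":
        calls = _apply_bh(calls, config)
    for call, cid in zip(calls, candidates):
        if call.positive:
            confirmed.append(cid)
    return calls, confirmed


def two_stage_screen(
    pool_wells: pd.DataFrame,
    peptide_wells: pd.DataFrame | None,
    design: PoolDesign,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Pool calling -> matrix deconvolution -> single-peptide confirmation.

    If the confirmation-stage wells are absent the decoded candidate list is
    returned with an empty confirmed set (stage separation).
    """
    config = config or ScreenConfig()
    pool_calls, positive = call_pools(pool_wells, design, config)
    deconvolution = decode(design, positive)
    if peptide_wells is None or len(peptide_wells) == 0:
        return ScreenResult(
            allele=design.allele,
            pool_calls=tuple(pool_calls),
            positive_pools=positive,
            deconvolution=deconvolution,
            peptide_calls=(),
            confirmed=(),
        )
    peptide_calls, confirmed = confirm_peptides(
        peptide_wells, deconvolution.candidates, config
    )
    return ScreenResult(
        allele=design.allele,
        pool_calls=tuple(pool_calls),
        positive_pools=positive,
        deconvolution=deconvolution,
        peptide_calls=tuple(peptide_calls),
        confirmed=tuple(confirmed),
    )


def calls_to_frame(calls: Sequence[PositivityCall]) -> pd.DataFrame:
    """Tabulate positivity calls."""
    return pd.DataFrame(
        [
            {
                "stimulus": c.stimulus,
                "mean_treated": c.mean_treated,
                "mean_control": c.mean_control,
                "p_value": c.p_value,
                "passes_floor": c.passes_floor,
                "positive": c.positive,
                "n_treated": c.n_treated,
                "n_control": c.n_control,
                "indeterminate": c.indeterminate,
            }
            for c in calls
        ]
    )
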