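"""Intracellular cytokine staining (ICS) and multimer readout summaries.

This module consumes pre-gated flow summaries — %IFN-γ+ among CD8+ T cells
per (mouse, tissue, route, stimulus) — and provides the downstream analyses
of the campaign: cross-assay Pearson correlation with ELISpot counts,
route-of-administration comparisons (two-way ANOVA with Tukey-adjusted
pairwise route contrasts per stimulus), epitope response composition, and
Boolean polyfunctionality gates over {IFN-γ, TNF-α, CD107a}.

ICS tables are tidy DataFrames with columns (allele, mouse_id, tissue,
route, stimulus, freq_ifng); tissue is "spleen" or "tumor", route "iv",
"it" or "untreated".  Multimer frequencies have identical shape and are
treated as just another stimulus ("multimer:<id>").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

MARKERS = ("IFNg", "TNFa", "CD107a")

#: The 8 Boolean marker combinations, as tuples aligned with MARKERS.
GATE_COMBINATIONS: tuple[tuple[bool, bool, bool], ...] = tuple(
    itertools.product((False, True), repeat=3)
)


def ifng_frequency(positive_events: int, total_cd8_events: int) -> float:
    """Percentage of IFN-γ+ cells among CD8+ events (full precision)."""
    if total_cd8_events <= 0:
        raise ValueError("total CD8+ event count must be positive")
    if positive_events < 0 or positive_events > total_cd8_events:
        raise ValueError("positive events must lie in [0, total]")
    return 100.0 * positive_events / total_cd8_events


def round_frequency(freq: float, decimals: int = 2) -> float:
    """Reporting convention: frequencies printed to 2 decimals."""
    return float(np.round(freq, decimals))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


def correlate_assays(
    elispot_means: Sequence[float], ics_means: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of paired per-stimulus ELISpot and ICS means.

    Symmetric in its arguments and invariant to affine rescaling.  Zero
    variance in either vector leaves r undefined (flagged, not raised).
    """
    x = np.asarray(elispot_means, dtype=float)
    y = np.asarray(ics_means, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired stimuli")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), n, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def compare_routes(
    ics: pd.DataFrame,
    stimuli: Sequence[str],
    alpha: float = 0.05,
    value_col: str = "freq_ifng",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route-of-administration comparison of IFN-γ+ frequencies.

    Fits the two-factor model  freq ~ C(stimulus) * C(route)  (OLS, type-II
    ANOVA) for the omnibus table, then computes Tukey-HSD-adjusted pairwise
    route contrasts within each stimulus.  Returns (anova_table, contrasts);
    contrasts has columns (stimulus, route_a, route_b, mean_diff, p_adj,
    significant).  A stimulus with fewer than two routes, or a route with
    fewer than two mice, is skipped with a warning.
    """
    data = ics[ics["stimulus"].isin(stimuli)].copy()
    if data.empty:
        raise ValueError("no rows for the requested stimuli")
    data = data.rename(columns={value_col: "freq"})
    terms = [
        f"C({factor})"
        for factor in ("stimulus", "route")
        if data[factor].nunique() > 1  # degenerate factors drop out
    ]
    if terms:
        model = ols("freq ~ " + " * ".join(terms), data=data).fit()
        anova = anova_lm(model, typ=2)
    else:
        warnings.warn("no varying factors; omnibus ANOVA skipped", stacklevel=2)
        anova = pd.DataFrame()

    rows = []
    for stimulus in stimuli:
        sub = data[data["stimulus"] == stimulus]
        counts = sub.groupby("route").size()
        routes = [r for r in counts.index if counts[r] >= 2]
        dropped = set(counts.index) - set(routes)
        if dropped:
            warnings.warn(
                f"{stimulus}: route(s) {sorted(dropped)} have <2 mice; "
                "contrast skipped",
                stacklevel=2,
            )
        if len(routes) < 2:
            warnings.warn(f"{stimulus}: fewer than two routes; skipped", stacklevel=2)
            continue
        sub = sub[sub["route"].isin(routes)]
        tukey = pairwise_tukeyhsd(
            sub["freq"].to_numpy(float), sub["route"].to_numpy(str), alpha=alpha
        )
        pairs = list(itertools.combinations(tukey.groupsunique, 2))
        for (a, b), diff, p_adj, reject in zip(
            pairs, tukey.meandiffs, tukey.pvalues, tukey.reject
        ):
            rows.append(
                {
                    "stimulus": stimulus,
                    "route_a": str(a),
                    "route_b": str(b),
                    "mean_diff": float(diff),
                    "p_adj": float(p_adj),
                    "significant": bool(reject),
                }
            )
    contrasts = pd.DataFrame(
        rows, columns=["stimulus", "route_a", "route_b", "mean_diff", "p_adj", "significant"]
    )
    return anova, contrasts


@dataclass(frozen=True)
class CompositionSummary:
    """Mean IFN-γ+ frequency per epitope and its share of the total response."""

    means: Mapping[str, float]  # NC-subtracted, clamped at 0
    proportions: Mapping[str, float]  # sum to 1 when any signal exists
    defined: bool = True


def epitope_composition(
    ics: pd.DataFrame,
    epitopes: Sequence[str],
    value_col: str = "freq_ifng",
) -> CompositionSummary:
    """Relative proportion of the virus-specific response per epitope.

    Per-epitope mean frequencies are background-corrected by subtracting the
    NC mean and clamping at zero, then normalised to proportions.  An
    all-zero corrected signal leaves proportions undefined (flagged).
    """
    nc = ics.loc[ics["stimulus"] == "NC", value_col]
    nc_mean = float(nc.mean()) if len(nc) else 0.0
    means: dict[str, float] = {}
    for epitope in epitopes:
        sub = ics.loc[ics["stimulus"] == epitope, value_col]
        if sub.empty:
            raise ValueError(f"no frequencies for stimulus {epitope!r}")
        means[epitope] = max(0.0, float(sub.mean()) - nc_mean)
    total = sum(means.values())
    if total <= 0:
        warnings.warn("all-zero corrected signal; proportions undefined", stacklevel=2)
        return CompositionSummary(
            means=means,
            proportions={e: float("nan") for e in epitopes},
            defined=False,
        )
    return CompositionSummary(
        means=means,
        proportions={e: v / total for e, v in means.items()},
    )


@dataclass(frozen=True)
class GateSummary:
    """Percentages of CD8+ events in each Boolean marker combination."""

    frequencies: Mapping[tuple[bool, bool, bool], float]
    single_positive: float
    double_positive: float
    triple_positive: float

    def frequency_of(self, **flags: bool) -> float:
        key = tuple(bool(flags.get(m, False)) for m in MARKERS)
        return self.frequencies[key]


def polyfunction_gates(
    counts: Mapping[tuple[bool, bool, bool], int],
    total_cd8_events: int | None = None,
) -> GateSummary:
    """Boolean-gate frequencies over {IFN-γ, TNF-α, CD107a}.

    `counts` must cover all 8 combinations (keys are Boolean triples aligned
    with :data:`MARKERS`) and sum to `total_cd8_events` when given.
    """
    missing = [c for c in GATE_COMBINATIONS if c not in counts]
    if missing:
        raise ValueError(f"missing marker combinations: {missing}")
    if any(counts[c] < 0 for c in GATE_COMBINATIONS):
        raise ValueError("negative gate counts")
    total = sum(counts[c] for c in GATE_COMBINATIONS)
    if total_cd8_events is not None and total != total_cd8_events:
        raise ValueError(
            f"gate counts sum to {total}, expected {total_cd8_events} CD8+ events"
        )
    if total == 0:
        raise ValueError("no CD8+ events")
    freqs = {c: 100.0 * counts[c] / total for c in GATE_COMBINATIONS}
    by_degree = {1: 0.0, 2: 0.0, 3: 0.0}
    for combo, freq in freqs.items():
        degree = sum(combo)
        if degree in by_degree:
            by_degree[degree] += freq
    return GateSummary(
        frequencies=freqs,
        single_positive=by_degree[1],
        double_positive=by_degree[2],
        triple_positive=by_degree[3],
    )
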