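"""Synthetic assay data with planted ground-truth epitopes.

No raw data accompanies the original campaign, so every pipeline stage is
exercised on simulated tables that reproduce the study's shapes: well-level
ELISpot spot counts (negative-binomial, overdispersed relative to Poisson)
for pool and single-peptide plates, and ICS frequency tables with
multiplicative route (i.v. > i.t.) and tissue (tumor > spleen) effects.

Spot counts are drawn NB with a mean/Fano parameterisation: `dispersion`
is the variance-to-mean ratio phi (variance = phi * mean), the standard
overdispersion index for count assays; phi -> 1 recovers Poisson.  Group
sizes default to the study's 4 untreated and 6 treated mice.  Control-group
mice are virus-naive and never carry planted effects.

All generation is driven by one integer seed through numpy's PCG64 stream,
so identical configs produce identical tables on any platform.

Also provided is a synthetic five-protein proteome with realistic protein
lengths and the published epitope sequences embedded, for fully
self-contained campaign runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pools import PoolDesign
from .proteome import GENOME_ORDER, ProteinRecord

#: Amino-acid background frequencies (rounded vertebrate averages).
_AA_FREQS: Mapping[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.042,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

#: Realistic lengths (aa) of the five proteins in genome order.
_PROTEIN_LENGTHS: Mapping[str, int] = {"N": 422, "P": 265, "M": 229, "GP": 498, "L": 600}

#: Published epitope sequences embedded in the synthetic proteome, with the
#: protein and 1-based start position used for embedding.  The nested length
#: variants (YMPYLIDFGL contains MPYLIDFGL; REYLKSYSRL contains EYLKSYSRL)
#: are embedded once via their longer form.
_EMBEDDED_EPITOPES: tuple[tuple[str, str, int], ...] = (
    ("N", "YMPYLIDFGL", 51),
    ("N", "FHFWGQLTAL", 201),
    ("P", "REYLKSYSRL", 41),
    ("P", "FQPKKASLQPL", 121),
    ("P", "RAEKSNYEL", 181),
)


def synthetic_proteome(seed: int = 0) -> list[ProteinRecord]:
    """A seeded five-protein proteome (synthetic stand-in, not viral data).

    Residues are drawn from average amino-acid frequencies; the published
    epitope sequences are spliced in at fixed positions of their proteins of
    origin so that characterization examples locate them.
    """
    rng = np.random.default_rng(seed)
    letters = sorted(_AA_FREQS)
    probs = np.array([_AA_FREQS[a] for a in letters])
    probs = probs / probs.sum()
    proteins: list[ProteinRecord] = []
    for index, name in enumerate(GENOME_ORDER, start=1):
        length = _PROTEIN_LENGTHS[name]
        seq = list(rng.choice(letters, size=length, p=probs))
        for prot, epitope, start in _EMBEDDED_EPITOPES:
            if prot == name:
                seq[start - 1 : start - 1 + len(epitope)] = list(epitope)
        proteins.append(
            ProteinRecord(name=name, order_index=index, sequence="".join(seq))
        )
    return proteins


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated ELISpot campaign.

    Means are expected spots per well; `dispersion` is the NB
    variance-to-mean ratio phi (> 1; values near 1 approach Poisson).
    `true_epitopes` holds the planted immunogenic candidate ids.
    """

    seed: int = 0
    n_control: int = 4
    n_treated: int = 6
    background_mean: float = 10.0
    dispersion: float = 5.0
    effect_mean: float = 300.0
    pc_mean: float = 500.0
    true_epitopes: frozenset[str] = frozenset()
    replicates: int = 1  # technical replicate wells per mouse x stimulus
    potency_spread: float = 0.5  # per-epitope immunogenicity heterogeneity (0 = flat)

    def __post_init__(self) -> None:
        if min(self.background_mean, self.effect_mean, self.pc_mean) <= 0:
            raise ValueError("means must be positive")
        if self.dispersion <= 1:
            raise ValueError("dispersion (variance/mean) must exceed 1")
        if self.n_control < 2 or self.n_treated < 2:
            raise ValueError("need at least 2 mice per group")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.potency_spread < 0:
            raise ValueError("potency_spread must be >= 0")


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size: int) -> np.ndarray:
    """NB counts with E = mean, Var = phi * mean."""
    k = mean / (phi - 1.0)
    return rng.negative_binomial(k, 1.0 / phi, size)


def _unit_hash(text: str) -> float:
    """Deterministic value in [0, 1) from a stable hash."""
    import hashlib

    digest = hashlib.blake2b(text.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def epitope_potency(allele: str, candidate_id: str, spread: float) -> float:
    """Deterministic per-epitope immunogenicity multiplier.

    Real epitopes differ in magnitude consistently across assays; this
    multiplier (log-uniform in [exp(-spread), exp(spread)], unit-centred)
    scales the planted treated mean in ELISpot and the ICS baseline alike,
    which is what makes the two readouts correlate across epitopes.
    """
    if spread == 0:
        return 1.0
    u = _unit_hash(f"potency|{allele}|{candidate_id}")
    return float(np.exp(spread * (2.0 * u - 1.0)))


def _plate(
    rng: np.random.Generator,
    config: SimulationConfig,
    allele: str,
    stimuli: Sequence[tuple[str, float | None]],  # (label, treated mean; None = background)
) -> pd.DataFrame:
    mice = [("control", f"C{i+1}") for i in range(config.n_control)] + [
        ("treated", f"T{i+1}") for i in range(config.n_treated)
    ]
    rows = []
    for group, mouse in mice:
        for stimulus, treated_mean in stimuli:
            if stimulus == "PC":
                mean = config.pc_mean
            elif treated_mean is not None and group == "treated":
                mean = treated_mean
            else:
                mean = config.background_mean
            for spots in _nb_draw(rng, mean, config.dispersion, config.replicates):
                rows.append(
                    {
                        "allele": allele,
                        "mouse_id": mouse,
                        "group": group,
                        "stimulus": stimulus,
                        "spots": int(spots),
                    }
                )
    return pd.DataFrame(rows)


def simulate_pool_plate(config: SimulationConfig, design: PoolDesign) -> pd.DataFrame:
    """Well table for the pool-screening stage (NC, PC, and all pools).

    A pool carries the planted effect (in treated mice only) when it contains
    at least one true epitope id.
    """
    rng = np.random.default_rng(config.seed)
    membership = design.pool_membership
    stimuli: list[tuple[str, float | None]] = [("NC", None), ("PC", None)]
    for pid in design.pool_ids:
        planted = membership[pid] & config.true_epitopes
        mean = None
        if planted:
            # a pool responds at the level of its strongest planted member
            mean = config.effect_mean * max(
                epitope_potency(design.allele, cid, config.potency_spread)
                for cid in planted
            )
        stimuli.append((f"pool:{pid}", mean))
    return _plate(rng, config, design.allele, stimuli)


def simulate_peptide_plate(
    config: SimulationConfig, candidates: Sequence[str], allele: str = ""
) -> pd.DataFrame:
    """Well table for the single-peptide confirmation stage."""
    if not candidates:
        return pd.DataFrame(
            columns=["allele", "mouse_id", "group", "stimulus", "spots"]
        )
    rng = np.random.default_rng(config.seed)
    stimuli: list[tuple[str, float | None]] = [("NC", None), ("PC", None)]
    for cid in candidates:
        mean = None
        if cid in config.true_epitopes:
            mean = config.effect_mean * epitope_potency(
                allele, cid, config.potency_spread
            )
        stimuli.append((f"peptide:{cid}", mean))
    return _plate(rng, config, allele, stimuli)


@dataclass(frozen=True)
class ICSEffectConfig:
    """Effect structure of the simulated ICS readout.

    Frequencies are %IFN-γ+ among CD8+ T cells.  The treated-mouse mean for
    an epitope stimulus is baseline_freq x route multiplier x tissue
    multiplier (per-stimulus route overrides allow planting patterns such as
    an i.v. advantage on a subset of epitopes); multiplicative log-normal
    noise with coefficient of variation `noise_cv` is applied, and values
    are clipped to [0, 100].  Untreated mice and NC wells sit at
    `background_freq`.
    """

    baseline_freq: float = 0.4
    route_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"iv": 2.7, "it": 1.0}
    )
    tissue_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"spleen": 1.0, "tumor": 4.0}
    )
    stimulus_route_multipliers: Mapping[str, Mapping[str, float]] | None = None
    stimulus_potency: Mapping[str, float] | None = None
    noise_cv: float = 0.2
    background_freq: float = 0.05

    def mean_for(self, stimulus: str, route: str, tissue: str) -> float:
        route_mult = self.route_multipliers.get(route, 0.0)
        if self.stimulus_route_multipliers and stimulus in self.stimulus_route_multipliers:
            route_mult = self.stimulus_route_multipliers[stimulus].get(route, route_mult)
        potency = 1.0
        if self.stimulus_potency is not None:
            potency = self.stimulus_potency.get(stimulus, 1.0)
        return (
            self.baseline_freq
            * potency
            * route_mult
            * self.tissue_multipliers.get(tissue, 1.0)
        )


def simulate_ics(
    config: SimulationConfig,
    effects: ICSEffectConfig,
    epitope_stimuli: Sequence[str],
    tissues: Sequence[str] = ("spleen", "tumor"),
    routes: Sequence[str] = ("iv", "it", "untreated"),
) -> pd.DataFrame:
    """ICS frequency table over mouse x tissue x route x stimulus.

    Treated routes ("iv"/"it") use n_treated mice each; "untreated" uses
    n_control.  Columns: allele (blank), mouse_id, tissue, route, stimulus,
    freq_ifng.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log(1.0 + effects.noise_cv**2)))
    rows = []
    for route in routes:
        n = config.n_control if route == "untreated" else config.n_treated
        for i in range(n):
            mouse = f"{route}-{i+1}"
            for tissue in tissues:
                for stimulus in ("NC", *epitope_stimuli):
                    if stimulus == "NC" or route == "untreated":
                        mean = effects.background_freq
                    else:
                        mean = effects.mean_for(stimulus, route, tissue)
                        if mean <= 0:
                            mean = effects.background_freq
                    noise = float(
                        np.exp(rng.normal(-0.5 * sigma**2, sigma))
                    )  # unit-mean log-normal
                    freq = float(np.clip(mean * noise, 0.0, 100.0))
                    rows.append(
                        {
                            "allele": "",
                            "mouse_id": mouse,
                            "tissue": tissue,
                            "route": route,
                            "stimulus": stimulus,
                            "freq_ifng": freq,
                        }
                    )
    return pd.DataFrame(rows)


def child_seed(seed: int, index: int) -> int:
    """Derive a stream-independent child seed below 2**31."""
    return int(np.random.default_rng([seed, index]).integers(0, 2**31 - 1))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
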