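import pytest
from hypothesis import HealthCheck, settings

from episcreen import pools, ranking, simulate
from episcreen.motifs import ALLELES
from episcreen.proteome import PeptideWindow, enumerate_peptides

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def proteome():
    return simulate.synthetic_proteome(seed=123)


@pytest.fixture(scope="session")
def windows(proteome):
    return enumerate_peptides(proteome)


@pytest.fixture(scope="session")
def panels(windows):
    return {
        allele: ranking.select_panel(
            windows, ranking.score_universe(windows, allele), allele
        )
        for allele in ALLELES
    }


@pytest.fixture(scope="session")
def designs(panels):
    return {allele: pools.build_matrix(panel) for allele, panel in panels.items()}


def _sequence(i: int, length: int = 9) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    seq = []
    value = i
    for _ in range(length):
        seq.append(alphabet[value % 20])
        value = value * 7 + 3
    return "".join(seq)


@pytest.fixture
def make_panel():
    """Factory for small synthetic panels with sequential candidate ids."""

    def build(n: int, allele: str = "H2-Kd") -> list[ranking.PeptideCandidate]:
        panel = []
        for i in range(1, n + 1):
            window = PeptideWindow(
                sequence=_sequence(i), protein="N", start=i, length=9
            )
            panel.append(
                ranking.PeptideCandidate(
                    allele=allele,
                    candidate_id=f"N{i}",
                    window=window,
                    scores=ranking.ScoreBundle(affinity_nM=10.0 + i, percent_rank=0.1 * i),
                    rank_index=i,
                )
            )
        return panel

    return build
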