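"""Published reference data for the BALB/c VSV-GP epitope campaign.

The original screen identified 11 CD8+ T cell epitopes across the three
BALB/c MHC-I alleles (five H2-Kd, four H2-Dd, two H2-Ld), all within the
first three viral proteins.  Candidate identities and the subset of epitope
sequences published in the main text are collected here; they parameterise
worked examples, synthetic campaigns and regression tests.
"""

from __future__ import annotations

from typing import Mapping

#: Candidate ids of the validated epitopes, per allele.
VALIDATED_EPITOPE_IDS: Mapping[str, tuple[str, ...]] = {
    "H2-Kd": ("N6", "N7", "N8", "P16", "P25"),
    "H2-Dd": ("P23", "P25", "M33", "M35"),
    "H2-Ld": ("N1", "N13"),
}

#: Published sequences of validated epitopes (not all were disclosed).
VALIDATED_EPITOPE_SEQUENCES: Mapping[tuple[str, str], str] = {
    ("H2-Kd", "N6"): "FHFWGQLTAL",
    ("H2-Kd", "P16"): "EYLKSYSRL",
    ("H2-Kd", "P25"): "REYLKSYSRL",
    ("H2-Dd", "P23"): "FQPKKASLQPL",
    ("H2-Dd", "P25"): "RAEKSNYEL",
    ("H2-Ld", "N1"): "MPYLIDFGL",
    ("H2-Ld", "N13"): "YMPYLIDFGL",
}

#: Epitopes shared with the C57BL/6 (H2-b) campaign of the same virus.
SHARED_WITH_B6: tuple[str, ...] = ("FQPKKASLQPL", "RAEKSNYEL")

#: Epitopes whose splenocyte IFN-γ+ frequencies did NOT differ between
#: intravenous and intratumoral administration (the other 8 of the 11
#: validated epitopes showed a significant i.v. advantage).
ROUTE_PARITY_EPITOPES: tuple[tuple[str, str], ...] = (
    ("H2-Kd", "P16"),
    ("H2-Kd", "P25"),
    ("H2-Dd", "M35"),
)

#: Protein of origin of each validated epitope id (the letter prefix).
def protein_of(candidate_id: str) -> str:
    letter = candidate_id[0]
    return {"N": "N", "P": "P", "M": "M", "G": "GP", "L": "L"}[letter]
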