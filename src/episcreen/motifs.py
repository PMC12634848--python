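"""Anchor-residue binding motifs for the BALB/c MHC class I alleles.

Each allele's binding groove constrains a small number of peptide positions
(anchors).  The motifs encoded here summarise the literature consensus used
throughout the package: H2-Kd strongly favours tyrosine at position 2 (pocket
B) and leucine/isoleucine at the C terminus (pocket F); H2-Dd peptides carry
glycine at position 2, proline at position 3 and lysine at position 5 with a
hydrophobic C terminus; the hydrophobic H2-Ld pocket B favours proline at
position 2.  Murine TAP prefers hydrophobic C-terminal residues generally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: Residues the mouse TAP transporter favours at the peptide C terminus.
HYDROPHOBIC = frozenset("LIVMF")

#: Supported MHC class I alleles of the BALB/c (H2-d) haplotype.
ALLELES: tuple[str, ...] = ("H2-Kd", "H2-Dd", "H2-Ld")


@dataclass(frozen=True)
class AnchorMotif:
    """Positional anchor-residue rules plus a C-terminus rule.

    `position_rules` maps 1-based peptide positions to allowed residue sets;
    `c_terminus` is the allowed set for the final residue.  An empty motif is
    vacuously matched.
    """

    allele: str
    position_rules: Mapping[int, frozenset[str]] = field(default_factory=dict)
    c_terminus: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for pos, residues in self.position_rules.items():
            if pos < 1:
                raise ValueError("anchor positions are 1-based")
            if not residues:
                raise ValueError(f"empty residue set at position {pos}")

    @property
    def n_rules(self) -> int:
        return len(self.position_rules) + (1 if self.c_terminus else 0)

    def match(self, sequence: str) -> dict[str, bool]:
        """Per-rule match flags for a peptide (keys 'pos2', ..., 'c_term')."""
        flags: dict[str, bool] = {}
        for pos, residues in sorted(self.position_rules.items()):
            flags[f"pos{pos}"] = pos <= len(sequence) and sequence[pos - 1] in residues
        if self.c_terminus:
            flags["c_term"] = bool(sequence) and sequence[-1] in self.c_terminus
        return flags

    def n_matched(self, sequence: str) -> int:
        return sum(self.match(sequence).values())


#: Default motif per allele.
DEFAULT_MOTIFS: Mapping[str, AnchorMotif] = {
    "H2-Kd": AnchorMotif("H2-Kd", {2: frozenset("Y")}, frozenset("LI")),
    "H2-Dd": AnchorMotif(
        "H2-Dd", {2: frozenset("G"), 3: frozenset("P"), 5: frozenset("K")}, HYDROPHOBIC
    ),
    "H2-Ld": AnchorMotif("H2-Ld", {2: frozenset("P")}, HYDROPHOBIC),
}


def motif_for(allele: str) -> AnchorMotif:
    try:
        return DEFAULT_MOTIFS[allele]
    except KeyError:
        raise ValueError(f"unknown allele {allele!r}; expected one of {ALLELES}") from None
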