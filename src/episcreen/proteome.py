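"""Ordered viral proteome input and peptide-window enumeration.

The screening campaign operates on the five proteins of a chimeric
rhabdovirus proteome in genome order: the VSV nucleoprotein (N),
phosphoprotein (P) and matrix protein (M), the LCMV glycoprotein (GP)
that replaces the native G, and the VSV polymerase (L).  Non-segmented
negative-strand RNA viruses transcribe their genes sequentially from the
3' promoter, so genome order doubles as a protein-abundance gradient;
downstream modules exploit this by allocating more candidate slots to
upstream proteins.

Coordinates are 1-based and inclusive within each protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed genome order, 3' to 5'.
GENOME_ORDER: tuple[str, ...] = ("N", "P", "M", "GP", "L")

#: Single-letter prefixes used for candidate identifiers downstream.
PROTEIN_LETTER: Mapping[str, str] = {"N": "N", "P": "P", "M": "M", "GP": "G", "L": "L"}

#: The 20 canonical amino acids; ambiguity codes (B, J, O, U, X, Z) are rejected.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Header tokens recognised for each protein (matched case-insensitively).
DEFAULT_ALIASES: Mapping[str, frozenset[str]] = {
    "N": frozenset({"n", "np", "nucleoprotein", "vsv-n"}),
    "P": frozenset({"p", "phosphoprotein", "vsv-p"}),
    "M": frozenset({"m", "matrix", "vsv-m"}),
    "GP": frozenset({"gp", "g", "glycoprotein", "lcmv-gp"}),
    "L": frozenset({"l", "polymerase", "vsv-l"}),
}

#: Peptide lengths presentable on MHC class I.
MIN_LENGTH = 8
MAX_LENGTH = 11


class ProteomeFormatError(ValueError):
    """The FASTA file does not describe the expected five-protein proteome."""


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter amino-acid alphabet."""

    def __init__(self, name: str, position: int, char: str):
        self.name = name
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"illegal residue {char!r} at position {position} of protein {name}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One viral protein with its position in the genome."""

    name: str
    order_index: int  # 1..5, 3' to 5'
    sequence: str

    def __post_init__(self) -> None:
        if self.name not in GENOME_ORDER:
            raise ProteomeFormatError(f"unknown protein name {self.name!r}")
        expected = GENOME_ORDER.index(self.name) + 1
        if self.order_index != expected:
            raise ProteomeFormatError(
                f"protein {self.name} must have order_index {expected}, "
                f"got {self.order_index}"
            )
        if not self.sequence:
            raise ProteomeFormatError(f"protein {self.name} has an empty sequence")
        for i, char in enumerate(self.sequence, start=1):
            if char not in AMINO_ACIDS:
                raise SequenceAlphabetError(self.name, i, char)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A contiguous 8-11-mer of one protein, with 1-based inclusive coordinates."""

    sequence: str
    protein: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if not MIN_LENGTH <= self.length <= MAX_LENGTH:
            raise ValueError(f"window length {self.length} outside {MIN_LENGTH}-{MAX_LENGTH}")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with the length field")
        if self.start < 1:
            raise ValueError("start coordinates are 1-based")

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1


def _identify(header: str, aliases: Mapping[str, frozenset[str]]) -> str | None:
    """Match a FASTA header to a protein name on whitespace/|/_ separated tokens."""
    tokens = header.replace("|", " ").replace("_", " ").split()
    for token in tokens:
        low = token.lower()
        for name, names in aliases.items():
            if low in names:
                return name
    return None


def read_proteome(
    path: str | Path,
    aliases: Mapping[str, frozenset[str]] | None = None,
) -> list[ProteinRecord]:
    """Read the five-protein proteome from FASTA, returning genome order.

    Records may appear in any file order; headers are matched
    case-insensitively against `aliases` (default :data:`DEFAULT_ALIASES`).
    Raises :class:`ProteomeFormatError` on missing/duplicate proteins and
    :class:`SequenceAlphabetError` on residues outside the canonical alphabet.
    """
    aliases = aliases or DEFAULT_ALIASES
    path = Path(path)
    found: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = _identify(record.description, aliases)
        if name is None:
            raise ProteomeFormatError(
                f"cannot identify protein from header {record.description!r}"
            )
        if name in found:
            raise ProteomeFormatError(f"duplicate protein {name}")
        found[name] = str(record.seq).upper()
    missing = [name for name in GENOME_ORDER if name not in found]
    if missing:
        raise ProteomeFormatError(f"missing protein {', '.join(missing)}")
    if len(found) != len(GENOME_ORDER):
        raise ProteomeFormatError("expected exactly five records")
    return [
        ProteinRecord(name=name, order_index=i + 1, sequence=found[name])
        for i, name in enumerate(GENOME_ORDER)
    ]


def write_proteome(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write the proteome as FASTA in genome order."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.name, description=f"{p.name} order={p.order_index}")
        for p in sorted(proteins, key=lambda p: p.order_index)
    ]
    SeqIO.write(records, str(path), "fasta")


def enumerate_peptides(
    proteins: Sequence[ProteinRecord],
    lengths: Iterable[int] = range(MIN_LENGTH, MAX_LENGTH + 1),
) -> list[PeptideWindow]:
    """Enumerate every window of each requested length for each protein.

    Output order is (protein genome order, start, length).  A protein of
    length L contributes max(0, L - k + 1) windows per requested length k.
    """
    lengths = sorted(set(lengths))
    if not lengths:
        raise ValueError("empty length range")
    for k in lengths:
        if not MIN_LENGTH <= k <= MAX_LENGTH:
            raise ValueError(f"length {k} outside {MIN_LENGTH}-{MAX_LENGTH}")
    windows: list[PeptideWindow] = []
    for protein in sorted(proteins, key=lambda p: p.order_index):
        seq = protein.sequence
        for start in range(1, len(seq) + 1):
            for k in lengths:
                if start + k - 1 > len(seq):
                    break
                windows.append(
                    PeptideWindow(
                        sequence=seq[start - 1 : start - 1 + k],
                        protein=protein.name,
                        start=start,
                        length=k,
                    )
                )
    return windows


def locate_peptide(
    sequence: str, proteins: Sequence[ProteinRecord]
) -> list[tuple[str, int]]:
    """Find all exact occurrences of a peptide, as (protein, 1-based start).

    Occurrences are ordered by (genome order, start); overlapping matches are
    all reported.  An absent peptide yields an empty list.
    """
    if not sequence:
        raise ValueError("empty query")
    query = sequence.upper()
    hits: list[tuple[str, int]] = []
    for protein in sorted(proteins, key=lambda p: p.order_index):
        pos = protein.sequence.find(query)
        while pos != -1:
            hits.append((protein.name, pos + 1))
            pos = protein.sequence.find(query, pos + 1)
    return hits


def windows_to_frame(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Tabulate enumerated windows (columns: peptide, protein, start, length)."""
    return pd.DataFrame(
        [(w.sequence, w.protein, w.start, w.length) for w in windows],
        columns=["peptide", "protein", "start", "length"],
    )


def write_windows(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)
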