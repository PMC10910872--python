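"""Reduced amino acid alphabets and kmer extraction.

Hashing operates on a reduced alphabet so that conservative substitutions
(e.g. I/L/V) do not break kmer matches between distant homologs.  The
canonical symbol set is the 20 standard residues plus ``X``, to which every
ambiguity code (B, Z, J, U, O) and any non-standard character is normalized
before hashing.  Alignment and acceptance always happen on the original
residues; the reduction affects candidate generation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SYMBOLS = STANDARD_RESIDUES + "X"

#: ambiguity / non-standard residue codes collapsed to X on normalization
AMBIGUOUS_RESIDUES = "BZJUO"

# Murphy-style 10-class grouping plus X as its own class.  Classes merge
# residues with similar physicochemistry: aliphatics, aromatics, acidic/
# amide, basic, small hydroxyl; C, A, G, P, H stay alone.
_MURPHY10_CLASSES = ["LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H", "X"]


class AlphabetError(ValueError):
    """Raised for symbols outside the canonical set or malformed alphabets."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input protein: an identifier and its residue string.

    Residues are expected uppercase with ambiguity codes already collapsed
    to ``X`` (see :func:`normalize_residues`).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase, strip ``*`` and gap characters, collapse ambiguity codes to X.

    Raises :class:`AlphabetError` for characters that are not residues,
    ambiguity codes, stops or gaps.
    """
    out = []
    for pos, ch in enumerate(raw):
        c = ch.upper()
        if c in STANDARD_RESIDUES or c == "X":
            out.append(c)
        elif c in AMBIGUOUS_RESIDUES:
            out.append("X")
        elif c in "*-.":
            continue
        else:
            raise AlphabetError(
                f"invalid residue symbol {ch!r} at position {pos}"
            )
    return "".join(out)


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total map from the 21 canonical symbols onto A class symbols."""

    name: str
    mapping: Mapping[str, str]
    _table: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [s for s in CANONICAL_SYMBOLS if s not in self.mapping]
        if missing:
            raise AlphabetError(
                f"alphabet {self.name!r} lacks a class for: {''.join(missing)}"
            )
        extra = [s for s in self.mapping if s not in CANONICAL_SYMBOLS]
        if extra:
            raise AlphabetError(
                f"alphabet {self.name!r} maps non-canonical symbols: {extra}"
            )
        object.__setattr__(
            self, "_table", str.maketrans(dict(self.mapping))
        )

    @property
    def size(self) -> int:
        return len(set(self.mapping.values()))

    def reduce(self, residues: str) -> str:
        """Map a normalized residue string symbol-by-symbol."""
        for pos, ch in enumerate(residues):
            if ch not in self.mapping:
                raise AlphabetError(
                    f"symbol {ch!r} at position {pos} outside canonical set"
                )
        return residues.translate(self._table)

    @classmethod
    def from_classes(cls, name: str, classes: Iterable[str]) -> "ReducedAlphabet":
        """Build from a partition of the canonical symbols.

        Each class is a string of member residues; the class symbol is its
        first character.  Classes must cover all 21 canonical symbols exactly
        once.
        """
        mapping: dict[str, str] = {}
        for cl in classes:
            if not cl:
                raise AlphabetError("empty alphabet class")
            rep = cl[0]
            for sym in cl:
                if sym in mapping:
                    raise AlphabetError(f"symbol {sym!r} appears in two classes")
                mapping[sym] = rep
        return cls(name=name, mapping=mapping)

    @classmethod
    def from_file(cls, path) -> "ReducedAlphabet":
        """Read a plain-text alphabet: one class per line, residues concatenated."""
        with open(path) as fh:
            classes = [ln.strip().upper() for ln in fh if ln.strip()]
        return cls.from_classes(name=str(path), classes=classes)


def identity_alphabet() -> ReducedAlphabet:
    """The no-reduction alphabet (every symbol its own class)."""
    return ReducedAlphabet("identity", {s: s for s in CANONICAL_SYMBOLS})


def murphy10_alphabet() -> ReducedAlphabet:
    """Ten physicochemical classes plus X; the default hashing alphabet."""
    return ReducedAlphabet.from_classes("murphy10", _MURPHY10_CLASSES)


_BUILTIN = {"identity": identity_alphabet, "murphy10": murphy10_alphabet}


def get_alphabet(name_or_path: str) -> ReducedAlphabet:
    """Resolve a builtin alphabet name or load a class file."""
    if name_or_path in _BUILTIN:
        return _BUILTIN[name_or_path]()
    return ReducedAlphabet.from_file(name_or_path)


@dataclass(frozen=True)
class KmerOccurrence:
    """A length-k window of a (reduced) sequence at a 0-based offset."""

    seq_id: str
    position: int
    kmer: str


def reduce_sequence(record: SequenceRecord, alphabet: ReducedAlphabet) -> str:
    """Map a record's residues to the reduced alphabet (length-preserving)."""
    return alphabet.reduce(record.residues)


def extract_kmers(seq_id: str, reduced: str, k: int) -> list[KmerOccurrence]:
    """All length-k windows of ``reduced``; empty when the sequence is shorter
    than k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(reduced)
    return [
        KmerOccurrence(seq_id, i, reduced[i : i + k]) for i in range(n - k + 1)
    ]
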