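"""IUPAC nucleotide alphabet, reverse complement, and degeneracy-aware distance.

Every other module builds on three primitives defined here:

* :func:`normalize` — turn pasted text (FASTA fragments, lowercase, stray
  whitespace/digits) into an uppercase IUPAC string.
* :func:`reverse_complement` — Watson–Crick reverse complement extended to the
  full 15-letter degenerate alphabet.
* :func:`degenerate_distance` — a modified Hamming distance in which two
  symbols match whenever the base sets they denote intersect.  Under this
  metric ``GCAT`` vs ``GGTT`` is 2, while ``GCAT`` vs ``GYTT`` is 1 because
  ``C`` is one of the bases ``Y`` stands for.

Coordinates are 0-based and half-open throughout the library; user-facing
reports convert to 1-based inclusive.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

__all__ = [
    "IUPAC_LETTERS",
    "BASE_SETS",
    "InvalidAlphabet",
    "LengthMismatch",
    "normalize",
    "reverse_complement",
    "complement",
    "bases_match",
    "degenerate_distance",
    "mismatch_positions",
    "is_concrete",
]

#: symbol -> frozenset of concrete bases it denotes (e.g. Y -> {C, T})
BASE_SETS: dict[str, frozenset[str]] = {
    sym: frozenset(exp) for sym, exp in ambiguous_dna_values.items() if sym != "X"
}

IUPAC_LETTERS: frozenset[str] = frozenset(BASE_SETS)

_COMPLEMENT: dict[str, str] = {k: v for k, v in ambiguous_dna_complement.items()}

# characters silently dropped during normalization: whitespace, digits and
# the separators people paste along with alignment/FASTA fragments
_STRIP = set(" \t\r\n\v\f0123456789-.*")


class InvalidAlphabet(ValueError):
    """A character outside the IUPAC nucleotide alphabet was found."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            f"(0-based, after normalization)"
        )


class LengthMismatch(ValueError):
    """Two sequences that must be equal length are not."""


def normalize(raw: str) -> str:
    """Normalize pasted sequence text to an uppercase IUPAC string.

    Lowercase is uppercased, whitespace/digits/gap characters are stripped
    (so a FASTA body or a numbered alignment row can be pasted directly),
    and ``U`` is mapped to ``T``.  Any residual non-IUPAC character raises
    :class:`InvalidAlphabet` naming the offender and its position.
    """
    if not isinstance(raw, str) or not raw:
        raise InvalidAlphabet("", 0)
    cleaned = []
    for ch in raw:
        if ch in _STRIP:
            continue
        up = ch.upper()
        if up == "U":
            up = "T"
        cleaned.append(up)
    seq = "".join(cleaned)
    if not seq:
        raise InvalidAlphabet("", 0)
    for i, ch in enumerate(seq):
        if ch not in IUPAC_LETTERS:
            raise InvalidAlphabet(ch, i)
    return seq


def complement(s: str) -> str:
    """Complement of ``s`` (degeneracy-aware, not reversed)."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in s)
    except KeyError as exc:  # pragma: no cover - guarded by normalize
        raise InvalidAlphabet(str(exc.args[0]), s.index(exc.args[0]))


def reverse_complement(s: str) -> str:
    """Reverse complement over the full IUPAC alphabet (R<->Y, B<->V, ...)."""
    return complement(s)[::-1]


def bases_match(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC symbols intersect.

    This is the matching rule behind the modified Hamming distance: ``C``
    matches ``Y`` (= C/T), ``N`` matches everything, ``R`` does not match
    ``Y``.
    """
    return not BASE_SETS[a].isdisjoint(BASE_SETS[b])


def mismatch_positions(a: str, b: str) -> list[int]:
    """Positions where ``a`` and ``b`` cannot denote a common base."""
    if len(a) != len(b):
        raise LengthMismatch(f"length {len(a)} != {len(b)}")
    return [i for i, (x, y) in enumerate(zip(a, b)) if BASE_SETS[x].isdisjoint(BASE_SETS[y])]


def degenerate_distance(a: str, b: str) -> int:
    """Modified Hamming distance allowing for degeneracy.

    Counts positions whose IUPAC base sets have an empty intersection.
    Symmetric; equals the classic Hamming distance on concrete (ACGT-only)
    strings.
    """
    return len(mismatch_positions(a, b))


def is_concrete(s: str) -> bool:
    """True when ``s`` contains only the concrete bases A, C, G, T."""
    return all(ch in "ACGT" for ch in s)
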