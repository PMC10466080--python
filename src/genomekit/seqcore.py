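"""Nucleotide and peptide alphabets, sequences, translation, random sequences.

The DNA alphabet is ``A C G T N`` plus their lowercase (soft-masked) forms
and ``-`` for alignment gaps.  Soft-masked bases compare equal to their
uppercase forms for all algorithmic purposes but are preserved verbatim on
serialization, since repeat masking in reference FASTAs is information a
round-trip must not destroy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP = "-"
DNA_ALPHABET = frozenset("ACGTNacgtn" + GAP)
_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

# Standard genetic code (NCBI translation table 1), codons in TCAG order.
_TCAG = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_TCAG)
    for j, b2 in enumerate(_TCAG)
    for k, b3 in enumerate(_TCAG)
}

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*X")  # 20 residues + stop + unknown


class AlphabetError(ValueError):
    """A character outside the nucleotide alphabet was encountered."""


@dataclass
class Sequence:
    """A named DNA sequence.

    ``seq`` is stored as a plain string over the DNA alphabet; validation
    happens in :func:`validate_seq` (called by parsers) rather than on every
    construction so internal code can build sequences cheaply.
    """

    name: str
    seq: str = field(default="", repr=False)

    def __len__(self) -> int:
        return len(self.seq)


def validate_seq(seq: str, name: str = "<sequence>") -> None:
    """Raise :class:`AlphabetError` naming the first offending position."""
    for i, c in enumerate(seq):
        if c not in DNA_ALPHABET:
            raise AlphabetError(
                f"{name}: invalid base {c!r} at position {i}"
            )


def seq_equal(a: str, b: str) -> bool:
    """Case-insensitive comparison: soft-masked bases equal their uppercase forms."""
    return a.upper() == b.upper()


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (soft-masking) per base."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate a DNA sequence with the standard genetic code.

    Whole-sequence translation, not ORF finding: stop codons yield ``*`` and
    translation continues.  A trailing partial codon is dropped.  Any codon
    containing ``N`` translates to ``X``.

    Parameters
    ----------
    seq:
        DNA over ``ACGTN`` (case-insensitive).  A gap character is an error.
    frame:
        Reading frame offset, one of 0, 1, 2.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    gap_at = seq.find(GAP)
    if gap_at >= 0:
        raise AlphabetError(f"gap character at position {gap_at} cannot be translated")
    s = seq.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            try:
                out.append(CODON_TABLE[codon])
            except KeyError:
                raise AlphabetError(
                    f"invalid base in codon {codon!r} at position {i}"
                ) from None
    return "".join(out)


def rand_seq(
    n_seqs: int, length: int, gc_fraction: float, seed: int
) -> list[Sequence]:
    """Generate i.i.d. random sequences at a given GC content.

    P(G) = P(C) = gc_fraction/2 and P(A) = P(T) = (1-gc_fraction)/2.
    Deterministic given ``seed``; sequences are named ``seq_0 .. seq_{n-1}``.
    """
    if n_seqs < 1 or length < 1:
        raise ValueError("n_seqs and length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n_seqs):
        draw = rng.choice(bases, size=length, p=[at, gc, gc, at])
        out.append(Sequence(f"seq_{i}", "".join(draw)))
    return out
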