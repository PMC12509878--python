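"""Nucleotide alphabet utilities for three-letter ("3N") sequence analysis.

Nucleotide-conversion sequencing chemistries (bisulfite C→T, SLAM-seq T→C)
replace one base letter by another in the sequenced reads.  Mapping such
reads works in a reduced three-letter alphabet obtained by applying the same
substitution to the reference.  This module provides the conversion scheme
abstraction, 3N conversion, reverse complementation and input validation
used by every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# encoding used by the hashing layer: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class ConversionScheme:
    """An ordered base substitution defining the 3N alphabet reduction.

    ``from_base`` is the nucleotide that the chemistry may rewrite,
    ``to_base`` the letter it is read as.  For bisulfite sequencing this is
    C→T (scheme ``"CT"``); for SLAM-seq it is T→C (scheme ``"TC"``).
    """

    from_base: str
    to_base: str
    name: str = field(default="")

    def __post_init__(self):
        fb, tb = self.from_base.upper(), self.to_base.upper()
        if fb not in "ACGT" or tb not in "ACGT":
            raise ValueError(f"bases must be one of A,C,G,T, got {fb!r}->{tb!r}")
        if fb == tb:
            raise ValueError("from_base and to_base must differ")
        object.__setattr__(self, "from_base", fb)
        object.__setattr__(self, "to_base", tb)
        if not self.name:
            object.__setattr__(self, "name", fb + tb)

    @classmethod
    def from_name(cls, name: str) -> "ConversionScheme":
        """Build a scheme from a two-letter label such as ``"CT"`` or ``"TC"``."""
        name = name.upper()
        if len(name) != 2:
            raise ValueError(f"scheme name must be two bases, got {name!r}")
        return cls(name[0], name[1], name)

    @property
    def complement_pair(self) -> tuple[str, str]:
        """The (from, to) pair as it appears on the opposite strand.

        A C→T conversion on one strand shows up as G→A when the locus is
        viewed in the forward-reference frame of a reverse-strand mapping.
        """
        return (self.from_base.translate(_COMPLEMENT), self.to_base.translate(_COMPLEMENT))


def _validate(seq: str) -> str:
    s = seq.upper()
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise InvalidSequenceError(
            f"sequence contains invalid characters {bad}; only A,C,G,T,N allowed"
        )
    return s


def convert_3n(seq: str, scheme: ConversionScheme) -> str:
    """Apply the 3N conversion: replace every ``from_base`` by ``to_base``.

    Input may be lower case (soft-masked); output is upper case.  ``N`` is
    left untouched.  Characters outside {A,C,G,T,N} raise
    :class:`InvalidSequenceError`.  The operation is idempotent.
    """
    s = _validate(seq)
    return s.replace(scheme.from_base, scheme.to_base)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; ``N`` maps to ``N``."""
    s = _validate(seq)
    return s.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a validated sequence as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 4:
        _validate(seq)  # raises with a clear message
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")
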