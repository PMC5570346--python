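"""Circular-permutation adjustment of protein sequences.

PGM3 carries a circular permutation within domain 1 relative to the other
human phosphohexomutase paralogs: two adjacent sequence segments (native
residues 54-114 and 115-169 in human PGM3) occupy swapped positions in the
chain while the fold is unchanged.  To align PGM3 against the other paralogs
its sequence is rewritten with the two segments exchanged ("adjusted"
coordinates); every reported position is translated back to native numbering
through a :class:`CoordinateTranslator`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ProteinRecord


class InvalidPermutationError(ValueError):
    """Raised when a permutation spec does not fit the target sequence."""


@dataclass(frozen=True)
class PermutationSpec:
    """Two adjacent closed 1-based intervals to be swapped.

    ``segment_a`` must immediately precede ``segment_b``
    (``segment_a[1] + 1 == segment_b[0]``).
    """

    segment_a: tuple[int, int]
    segment_b: tuple[int, int]

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.segment_a, self.segment_b
        if not (1 <= a0 <= a1 and a1 < b0 <= b1):
            raise InvalidPermutationError(
                f"segments {self.segment_a}, {self.segment_b} must be "
                "ordered, non-empty and non-overlapping"
            )
        if a1 + 1 != b0:
            raise InvalidPermutationError(
                f"segments {self.segment_a}, {self.segment_b} must be adjacent"
            )

    def validate_length(self, length: int) -> None:
        if self.segment_b[1] > length:
            raise InvalidPermutationError(
                f"segment_b {self.segment_b} exceeds sequence length {length}"
            )


#: The canonical adjustment for human PGM3 (native residues 54-114 <-> 115-169).
PGM3_SPEC = PermutationSpec(segment_a=(54, 114), segment_b=(115, 169))


class CoordinateTranslator:
    """Bijection between native and permutation-adjusted 1-based coordinates."""

    def __init__(self, spec: PermutationSpec, length: int, *, _inverse: bool = False):
        spec.validate_length(length)
        self.spec = spec
        self.length = length
        self._inverse_flag = _inverse

    def _forward(self, pos: int) -> int:
        (a0, a1), (b0, b1) = self.spec.segment_a, self.spec.segment_b
        len_a, len_b = a1 - a0 + 1, b1 - b0 + 1
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        if a0 <= pos <= a1:
            return pos + len_b
        if b0 <= pos <= b1:
            return pos - len_a
        return pos

    def to_adjusted(self, native_pos: int) -> int:
        """Native position -> position in the segment-swapped sequence."""
        if self._inverse_flag:
            return self._backward(native_pos)
        return self._forward(native_pos)

    def _backward(self, pos: int) -> int:
        # The swap is an involution on index blocks: applying the forward map
        # of the *adjusted* spec undoes it.  Compute directly for clarity.
        (a0, a1), (b0, b1) = self.spec.segment_a, self.spec.segment_b
        len_a, len_b = a1 - a0 + 1, b1 - b0 + 1
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        if a0 <= pos <= a0 + len_b - 1:
            return pos + len_a
        if a0 + len_b <= pos <= b1:
            return pos - len_b
        return pos

    def to_native(self, adjusted_pos: int) -> int:
        """Adjusted position -> native position."""
        if self._inverse_flag:
            return self._forward(adjusted_pos)
        return self._backward(adjusted_pos)

    def inverted(self) -> "CoordinateTranslator":
        """Translator with the native/adjusted roles exchanged."""
        return CoordinateTranslator(
            self.spec, self.length, _inverse=not self._inverse_flag
        )


def circular_permute(
    record: ProteinRecord, spec: PermutationSpec
) -> tuple[ProteinRecord, CoordinateTranslator]:
    """Swap two adjacent segments of ``record``.

    Returns the adjusted record (same id, residues re-ordered as
    prefix + segment_b + segment_a + suffix) and the coordinate translator
    mapping between native and adjusted numbering.
    """
    spec.validate_length(len(record))
    (a0, a1), (b0, b1) = spec.segment_a, spec.segment_b
    s = record.residues
    adjusted = s[: a0 - 1] + s[b0 - 1 : b1] + s[a0 - 1 : a1] + s[b1:]
    new = ProteinRecord(
        id=record.id,
        residues=adjusted,
        paralog=record.paralog,
        organism=record.organism,
    )
    return new, CoordinateTranslator(spec, len(record))


def invert_permutation(translator: CoordinateTranslator) -> CoordinateTranslator:
    """Translator whose forward map undoes ``translator``'s forward map."""
    return translator.inverted()
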