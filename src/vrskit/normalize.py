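"""Fully justified Allele normalization (Variant Overprecision Correction).

An insertion or deletion inside a repeat can be placed at many equivalent
positions; left- or right-aligning picks one arbitrarily and over-states the
precision of the call.  Normalization here instead *fully justifies* the
edit: it trims shared flanks, classifies the residual edit, rolls the allele
sequence left and right through the repeat to find the bounds of ambiguity,
and returns a new Allele spanning the entire ambiguous region.

The procedure, for a literal Allele on a precise inter-residue interval
``[start, end)`` with reference sequence ``ref`` (from the store) and
alternate sequence ``alt`` (the state):

1. trim the common suffix, then the common prefix, adjusting ``end`` and
   ``start``;
2. if both trimmed sequences are empty the Allele matches the reference and
   is returned unmodified; if both are non-empty it is a substitution with
   the trimmed coordinates and state;
3. otherwise (an indel) roll the surviving sequence: the left bound moves
   left while the base before it equals the last character of a circularly
   permuted working copy; the right bound moves right symmetrically against
   the first character;
4. the normalized Allele covers ``[left_bound, right_bound)`` with state
   ``context[left:start] + alt + context[end:right]``.

Rolling uses working copies only; the original alternate sequence enters
step 4 unpermuted.  Rolling halts at the sequence boundaries (no circular
genomes).  Characters compare by exact byte equality; IUPAC ambiguity codes
never match other codes, keeping digests deterministic.
"""

from __future__ import annotations

import warnings
from typing import Sequence as TypingSequence

from .models import (
    Allele,
    LiteralSequenceExpression,
    Number,
    SequenceInterval,
    SequenceLocation,
)

__all__ = [
    "trim_common_flanks",
    "roll_bounds",
    "normalize_allele",
    "NotNormalizedWarning",
]


class NotNormalizedWarning(UserWarning):
    """The Allele's shape has no normalization rules; it was returned as-is."""


def trim_common_flanks(ref: str, alt: str) -> tuple[str, str, int, int]:
    """Remove common flanking sequence: suffix first, then prefix.

    Returns ``(ref', alt', suffix_len, prefix_len)``; the caller decrements
    ``end`` by ``suffix_len`` and increments ``start`` by ``prefix_len``.
    The returned pair shares no first or last character.
    """
    suffix_len = 0
    while (
        suffix_len < len(ref)
        and suffix_len < len(alt)
        and ref[len(ref) - 1 - suffix_len] == alt[len(alt) - 1 - suffix_len]
    ):
        suffix_len += 1
    if suffix_len:
        ref = ref[:-suffix_len]
        alt = alt[:-suffix_len]
    prefix_len = 0
    while prefix_len < len(ref) and prefix_len < len(alt) and ref[prefix_len] == alt[prefix_len]:
        prefix_len += 1
    return ref[prefix_len:], alt[prefix_len:], suffix_len, prefix_len


class _StoreContext:
    """Random access over a stored reference sequence, fetching residues
    lazily so normalization only touches the neighbourhood it rolls over."""

    def __init__(self, store, sequence_id: str, length: int) -> None:
        self._store = store
        self._sequence_id = sequence_id
        self._length = length
        self._cache: dict[int, str] = {}

    def __len__(self) -> int:
        return self._length

    def __getitem__(self, i: int) -> str:
        if isinstance(i, slice):
            start, stop, _ = i.indices(self._length)
            return self.slice(start, stop)
        if not 0 <= i < self._length:
            raise IndexError(i)
        if i not in self._cache:
            self._cache[i] = self._store.get_sequence(self._sequence_id, i, i + 1)
        return self._cache[i]

    def slice(self, start: int, end: int) -> str:
        if start >= end:
            return ""
        return self._store.get_sequence(self._sequence_id, start, end)


def roll_bounds(
    context: TypingSequence[str], start: int, allele_seq: str
) -> tuple[int, int]:
    """Bounds of ambiguity for an indel of ``allele_seq`` anchored at
    inter-residue position ``start``.

    The left roll compares the *last* character of a circularly permuted
    working copy with the base preceding the bound; the right roll compares
    the *first* character with the base following the bound.  Both halt at
    the sequence boundaries.  The caller's ``allele_seq`` is never altered.
    """
    if not allele_seq:
        raise ValueError("allele sequence must be non-empty for rolling")
    n = len(context)

    left = start
    working = allele_seq
    while left > 0 and context[left - 1] == working[-1]:
        left -= 1
        working = working[-1] + working[:-1]

    right = start
    working = allele_seq
    while right < n and context[right] == working[0]:
        right += 1
        working = working[1:] + working[0]

    return left, right


def _not_normalized(allele: Allele, reason: str) -> Allele:
    warnings.warn(f"allele not normalized: {reason}", NotNormalizedWarning)
    return allele


def normalize_allele(allele: Allele, store) -> Allele:
    """Return the fully justified form of a literal Allele.

    Only Alleles with a precise SequenceLocation and a
    LiteralSequenceExpression state have normalization rules; any other
    shape is returned unchanged with a :class:`NotNormalizedWarning`
    (a soft signal, distinct from hard errors such as an unresolvable
    sequence).  The result is idempotent under re-normalization, and
    applying it to the reference reproduces exactly the edit described by
    the input.
    """
    if not isinstance(allele.location, SequenceLocation):
        return _not_normalized(allele, "location is not a SequenceLocation")
    if not isinstance(allele.state, LiteralSequenceExpression):
        return _not_normalized(allele, "state is not a LiteralSequenceExpression")
    interval = allele.location.interval
    if not interval.is_precise():
        return _not_normalized(allele, "interval has ranged coordinates")

    sequence_id = allele.location.sequence_id
    meta = store.get_metadata(sequence_id)  # raises for unknown sequences
    start, end = interval.start.value, interval.end.value
    if end > meta.length:
        raise ValueError(
            f"interval ({start}, {end}) out of bounds for sequence of "
            f"length {meta.length}"
        )

    ref = store.get_sequence(sequence_id, start, end)
    alt = allele.state.sequence

    trimmed_ref, trimmed_alt, suffix_len, prefix_len = trim_common_flanks(ref, alt)
    start += prefix_len
    end -= suffix_len

    if not trimmed_ref and not trimmed_alt:
        # reference Allele: the stated (possibly repetitive) span is the
        # intent; return it untouched
        return allele

    if trimmed_ref and trimmed_alt:
        return _rebuild(allele, start, end, trimmed_alt)

    context = _StoreContext(store, sequence_id, meta.length)
    rolled = trimmed_ref or trimmed_alt
    left, right = roll_bounds(context, start, rolled)
    # for deletions the right roll consumes the deleted span itself before
    # extending beyond it, so `right` is already the region's right edge
    new_alt = context.slice(left, start) + trimmed_alt + context.slice(end, right)
    return _rebuild(allele, left, right, new_alt)


def _rebuild(allele: Allele, start: int, end: int, alt: str) -> Allele:
    return Allele(
        location=SequenceLocation(
            sequence_id=allele.location.sequence_id,
            interval=SequenceInterval(
                start=Number(value=start), end=Number(value=end)
            ),
        ),
        state=LiteralSequenceExpression(sequence=alt),
    )
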