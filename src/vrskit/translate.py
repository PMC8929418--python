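"""Translation between Alleles and the HGVS / SPDI nomenclatures.

SPDI (``sequence:position:deletion:insertion``) already uses inter-residue
positions, so it maps onto an Allele directly: the deletion (given as a
length or as the deleted residues) fixes the located span and the insertion
is the literal state.

The supported HGVS subset is linear genomic-style coordinates (``g.``,
``m.``, ``n.``) with substitution, del, ins, delins, dup and the identity
(``=``) forms.  HGVS counts residues from 1 inclusively, so residue ``n``
becomes the inter-residue interval ``(n-1, n)``.  A ``dup`` is translated as
a molecular insertion of the duplicated span immediately after that span —
never as a systemic copy number change, which callers must state explicitly
with a CopyNumber object.  Uncertain breakpoints (``(?_123)``) are rejected
outright rather than approximated.

Formatting to HGVS follows that nomenclature's 3'-rule: the fully justified
Allele is re-minimized at the 3'-most equivalent position (emitting ``dup``
when the inserted bases repeat the residues immediately preceding the
insertion point).
"""

from __future__ import annotations

import re
from typing import Optional

from .models import (
    Allele,
    LiteralSequenceExpression,
    Number,
    SequenceInterval,
    SequenceLocation,
)
from .normalize import normalize_allele, trim_common_flanks
from .store import SequenceStore

__all__ = [
    "parse_spdi",
    "format_spdi",
    "parse_hgvs",
    "format_hgvs",
    "TranslationError",
    "ReferenceMismatchError",
    "UnsupportedHgvsError",
]


class TranslationError(ValueError):
    """Expression cannot be translated."""


class ReferenceMismatchError(TranslationError):
    """An asserted reference sequence disagrees with the stored sequence."""


class UnsupportedHgvsError(TranslationError):
    """Syntactically recognizable HGVS outside the supported subset."""


def _literal_allele(sequence_id: str, start: int, end: int, alt: str) -> Allele:
    return Allele(
        location=SequenceLocation(
            sequence_id=sequence_id,
            interval=SequenceInterval(
                start=Number(value=start), end=Number(value=end)
            ),
        ),
        state=LiteralSequenceExpression(sequence=alt),
    )


# -- SPDI ----------------------------------------------------------------

_SPDI_DELETION = re.compile(r"^(\d+|[A-Za-z*\-]*)$")


def parse_spdi(expr: str, store: SequenceStore, normalize: bool = False) -> Allele:
    """Build an Allele from ``seq:pos:del:ins``.

    ``del`` may be a length or the deleted residues themselves; in the
    latter case it is checked against the store.
    """
    parts = expr.rsplit(":", 3)
    if len(parts) != 4:
        raise TranslationError(f"not a SPDI expression: {expr!r}")
    accession, pos_token, del_token, insertion = parts
    if not pos_token.isdigit():
        raise TranslationError(f"SPDI position must be a non-negative int: {expr!r}")
    position = int(pos_token)
    if not _SPDI_DELETION.match(del_token):
        raise TranslationError(f"malformed SPDI deletion field: {expr!r}")

    if del_token.isdigit() or del_token == "":
        del_len = int(del_token) if del_token else 0
    else:
        del_len = len(del_token)
    end = position + del_len
    located = store.get_sequence(accession, position, end)  # bounds-checked
    if del_token and not del_token.isdigit() and located != del_token.upper():
        raise ReferenceMismatchError(
            f"SPDI deletion {del_token!r} != stored {located!r} at "
            f"({position}, {end})"
        )
    allele = _literal_allele(accession, position, end, insertion)
    return normalize_allele(allele, store) if normalize else allele


def format_spdi(
    allele: Allele, store: SequenceStore, namespace: str = "local"
) -> str:
    """Render a literal Allele as ``seq:pos:del_length:ins``."""
    accession, start, end, alt = _destructure(allele, store, namespace)
    return f"{accession}:{start}:{end - start}:{alt}"


# -- HGVS ----------------------------------------------------------------

_HGVS_SHAPE = re.compile(r"^(?P<acc>.+):(?P<ctype>[gmn])\.(?P<edit>.+)$")
_SUBSTITUTION = re.compile(r"^(\d+)([A-Z])>([A-Z])$")
_IDENTITY = re.compile(r"^(\d+)(?:_(\d+))?([A-Z]*)=$")
_DELETION = re.compile(r"^(\d+)(?:_(\d+))?del([A-Z]*)$")
_INSERTION = re.compile(r"^(\d+)_(\d+)ins([A-Z]+)$")
_DELINS = re.compile(r"^(\d+)(?:_(\d+))?delins([A-Z]+)$")
_DUPLICATION = re.compile(r"^(\d+)(?:_(\d+))?dup([A-Z]*)$")


def _span(match: re.Match) -> tuple[int, int]:
    """1-based inclusive residue span -> inter-residue half-open interval."""
    first = int(match.group(1))
    last = int(match.group(2)) if match.group(2) else first
    if first < 1 or last < first:
        raise TranslationError(f"invalid HGVS residue span {first}_{last}")
    return first - 1, last


def _check_asserted(store, accession, start, end, asserted, expr):
    stored = store.get_sequence(accession, start, end)
    if asserted and stored != asserted:
        raise ReferenceMismatchError(
            f"{expr!r} asserts {asserted!r} but the stored sequence at "
            f"({start}, {end}) is {stored!r}"
        )
    return stored


def parse_hgvs(expr: str, store: SequenceStore, normalize: bool = False) -> Allele:
    """Build an Allele from a genomic-style linear HGVS expression."""
    shape = _HGVS_SHAPE.match(expr)
    if not shape:
        raise TranslationError(f"not a supported HGVS expression: {expr!r}")
    accession = shape.group("acc")
    edit = shape.group("edit")
    if "(" in edit or "?" in edit:
        raise UnsupportedHgvsError(
            f"uncertain breakpoints are not supported: {expr!r}"
        )

    if m := _SUBSTITUTION.match(edit):
        residue = int(m.group(1))
        if residue < 1:
            raise TranslationError(f"invalid HGVS residue {residue}")
        start, end = residue - 1, residue
        _check_asserted(store, accession, start, end, m.group(2), expr)
        allele = _literal_allele(accession, start, end, m.group(3))
    elif m := _INSERTION.match(edit):
        first, last = int(m.group(1)), int(m.group(2))
        if last != first + 1:
            raise TranslationError(
                f"HGVS ins requires adjacent flanking residues: {expr!r}"
            )
        allele = _literal_allele(accession, first, first, m.group(3))
    elif m := _DELINS.match(edit):
        start, end = _span(m)
        store.get_sequence(accession, start, end)  # bounds check
        allele = _literal_allele(accession, start, end, m.group(3))
    elif m := _DELETION.match(edit):
        start, end = _span(m)
        asserted = m.group(3)
        if asserted and len(asserted) != end - start:
            raise TranslationError(
                f"asserted deletion length disagrees with span: {expr!r}"
            )
        _check_asserted(store, accession, start, end, asserted, expr)
        allele = _literal_allele(accession, start, end, "")
    elif m := _DUPLICATION.match(edit):
        start, end = _span(m)
        duplicated = _check_asserted(store, accession, start, end, m.group(3), expr)
        # tandem duplication = molecular insertion right after the span
        allele = _literal_allele(accession, end, end, duplicated)
    elif m := _IDENTITY.match(edit):
        start, end = _span(m)
        stored = _check_asserted(store, accession, start, end, m.group(3), expr)
        allele = _literal_allele(accession, start, end, stored)
    else:
        raise TranslationError(f"unsupported HGVS edit: {expr!r}")

    return normalize_allele(allele, store) if normalize else allele


def _destructure(
    allele: Allele, store: SequenceStore, namespace: str
) -> tuple[str, int, int, str]:
    if not isinstance(allele.location, SequenceLocation):
        raise TranslationError("allele location is not a SequenceLocation")
    if not isinstance(allele.state, LiteralSequenceExpression):
        raise TranslationError("allele state is not a LiteralSequenceExpression")
    if not allele.location.interval.is_precise():
        raise TranslationError("allele interval has ranged coordinates")
    aliases = store.translate_sequence_identifier(
        allele.location.sequence_id, namespace
    )
    if not aliases:
        raise TranslationError(
            f"sequence {allele.location.sequence_id!r} has no alias in "
            f"namespace {namespace!r}"
        )
    return (
        aliases[0],
        allele.location.interval.start.value,
        allele.location.interval.end.value,
        allele.state.sequence,
    )


def format_hgvs(
    allele: Allele,
    store: SequenceStore,
    namespace: str = "local",
    coordinate_type: str = "g",
) -> str:
    """Render a literal Allele as 3'-most-shifted HGVS.

    The Allele is fully justified first, then the minimal edit is re-derived
    at the right (3') edge of the ambiguous region per the HGVS convention.
    """
    if coordinate_type not in ("g", "m", "n"):
        raise TranslationError(f"unsupported coordinate type: {coordinate_type!r}")
    normalized = normalize_allele(allele, store)
    accession, start, end, alt = _destructure(normalized, store, namespace)
    sequence_id = normalized.location.sequence_id
    ref = store.get_sequence(sequence_id, start, end)
    prefix = f"{accession}:{coordinate_type}."

    if ref == alt:
        if not ref:
            raise TranslationError("empty reference Allele has no HGVS form")
        if len(ref) == 1:
            return f"{prefix}{start + 1}{ref}="
        return f"{prefix}{start + 1}_{end}="

    # right-shift: strip the common prefix first, then the common suffix
    shift = 0
    while shift < min(len(ref), len(alt)) and ref[shift] == alt[shift]:
        shift += 1
    r, a = ref[shift:], alt[shift:]
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    s = start + shift
    e = s + len(r)

    if not r:  # insertion at inter-residue position s
        if s >= len(a) and store.get_sequence(sequence_id, s - len(a), s) == a:
            dup_start, dup_end = s - len(a), s
            if len(a) == 1:
                return f"{prefix}{dup_end}dup"
            return f"{prefix}{dup_start + 1}_{dup_end}dup"
        return f"{prefix}{s}_{s + 1}ins{a}"
    if not a:  # deletion of [s, e)
        if len(r) == 1:
            return f"{prefix}{s + 1}del"
        return f"{prefix}{s + 1}_{e}del"
    if len(r) == 1 and len(a) == 1:
        return f"{prefix}{s + 1}{r}>{a}"
    if len(r) == 1:
        return f"{prefix}{s + 1}delins{a}"
    return f"{prefix}{s + 1}_{e}delins{a}"
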