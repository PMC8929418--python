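"""Value-object data model for molecular and systemic variation.

Every class here is an immutable *value object*: its meaning is carried
entirely by the attributes it holds, never by an assigned accession or a
human-readable label.  Two objects with identical content are the same
variation, regardless of how or where they were constructed; the optional
``_id`` field is a convenience slot for a computed identifier and is ignored
by equality and by digest serialization.

Coordinates are strictly inter-residue: an interval ``(a, b)`` names the
space between residues and spans ``b - a`` residues.  This makes locations
meaningful without knowing whether an edit is an insertion, deletion or
substitution.

Polymorphic fields (locations, sequence expressions, range-or-number slots)
are dispatched on a ``type`` discriminator carried by every document.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Annotated, Any, Literal, Mapping, Optional, Union

from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    ValidationError,
    WithJsonSchema,
    field_validator,
    model_validator,
)

__all__ = [
    "Curie",
    "SequenceString",
    "Number",
    "DefiniteRange",
    "IndefiniteRange",
    "SequenceInterval",
    "CytobandInterval",
    "SequenceLocation",
    "ChromosomeLocation",
    "LiteralSequenceExpression",
    "DerivedSequenceExpression",
    "RepeatedSequenceExpression",
    "Allele",
    "Haplotype",
    "Text",
    "VariationSet",
    "CopyNumber",
    "Gene",
    "Location",
    "SequenceExpression",
    "Variation",
    "TYPE_REGISTRY",
    "IDENTIFIABLE_TYPES",
    "is_identifiable",
    "validate",
    "parse_object",
    "Violation",
    "ValidationReport",
    "MalformedDocumentError",
]

# CURIE: "<namespace>:<reference>"; namespace starts with a word character and
# contains no colon, reference is non-empty.
CURIE_PATTERN = re.compile(r"^\w[^:\s]*:\S+$")

# Cytoband designator: chromosome arm p or q followed by dotted band numbers
# (e.g. "q22.3"), or the telomere designators pter/qter.
CYTOBAND_PATTERN = re.compile(r"^(pter|qter|cen|[pq](\d+(\.\d+)*)?)$")

# IUPAC one-letter residue codes (nucleic + amino acid alphabets), uppercase,
# plus '*' (stop) and '-' (gap).
SEQUENCE_PATTERN = re.compile(r"^[A-Z*\-]*$")


def _check_curie(value: str) -> str:
    if not isinstance(value, str) or not CURIE_PATTERN.match(value):
        raise ValueError(
            f"not a CURIE (expected '<namespace>:<reference>'): {value!r}"
        )
    return value


def _fold_sequence(value: Any) -> Any:
    if isinstance(value, str):
        value = value.upper()
        if not SEQUENCE_PATTERN.match(value):
            raise ValueError(f"not an IUPAC sequence string: {value!r}")
    return value


def _check_cytoband(value: str) -> str:
    if not isinstance(value, str) or not CYTOBAND_PATTERN.match(value):
        raise ValueError(f"not a cytoband designator: {value!r}")
    return value


Curie = Annotated[
    str,
    BeforeValidator(_check_curie),
    WithJsonSchema({"type": "string", "pattern": CURIE_PATTERN.pattern}),
]
SequenceString = Annotated[
    str,
    BeforeValidator(_fold_sequence),
    WithJsonSchema({"type": "string", "pattern": SEQUENCE_PATTERN.pattern}),
]
Cytoband = Annotated[
    str,
    BeforeValidator(_check_cytoband),
    WithJsonSchema({"type": "string", "pattern": CYTOBAND_PATTERN.pattern}),
]


def _strip_private(value: Any) -> Any:
    """Recursively drop underscore-prefixed keys from a plain document."""
    if isinstance(value, dict):
        return {
            k: _strip_private(v) for k, v in value.items() if not k.startswith("_")
        }
    if isinstance(value, list):
        return [_strip_private(v) for v in value]
    return value


class _ValueObject(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid", populate_by_name=True)

    def as_document(self) -> dict:
        """Plain JSON-ready document, including a populated ``_id``."""
        return self.model_dump(by_alias=True, exclude_none=True, mode="json")

    def value_document(self) -> dict:
        """Document with all ``_id`` slots removed: the object's pure value."""
        return _strip_private(self.as_document())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, _ValueObject):
            return NotImplemented
        return (
            type(self) is type(other)
            and self.value_document() == other.value_document()
        )

    def __hash__(self) -> int:
        return hash(json.dumps(self.value_document(), sort_keys=True))


class Number(_ValueObject):
    type: Literal["Number"] = "Number"
    value: int


class DefiniteRange(_ValueObject):
    type: Literal["DefiniteRange"] = "DefiniteRange"
    min: int
    max: int

    @model_validator(mode="after")
    def _ordered(self) -> "DefiniteRange":
        if self.min > self.max:
            raise ValueError(f"min ({self.min}) must be <= max ({self.max})")
        return self


class IndefiniteRange(_ValueObject):
    type: Literal["IndefiniteRange"] = "IndefiniteRange"
    value: int
    comparator: Literal["<=", ">="]


RangeOrNumber = Union[Number, DefiniteRange, IndefiniteRange]


class SequenceInterval(_ValueObject):
    """Inter-residue span: (start, end) covers ``end - start`` residues."""

    type: Literal["SequenceInterval"] = "SequenceInterval"
    start: RangeOrNumber = Field(discriminator="type")
    end: RangeOrNumber = Field(discriminator="type")

    @model_validator(mode="after")
    def _bounds(self) -> "SequenceInterval":
        if isinstance(self.start, Number) and isinstance(self.end, Number):
            if self.start.value < 0:
                raise ValueError("start must be >= 0")
            if self.start.value > self.end.value:
                raise ValueError(
                    f"start ({self.start.value}) must be <= end ({self.end.value})"
                )
        return self

    def is_precise(self) -> bool:
        return isinstance(self.start, Number) and isinstance(self.end, Number)


class CytobandInterval(_ValueObject):
    type: Literal["CytobandInterval"] = "CytobandInterval"
    start: Cytoband
    end: Cytoband


class SequenceLocation(_ValueObject):
    type: Literal["SequenceLocation"] = "SequenceLocation"
    id: Optional[Curie] = Field(default=None, alias="_id")
    sequence_id: Curie
    interval: SequenceInterval


class ChromosomeLocation(_ValueObject):
    type: Literal["ChromosomeLocation"] = "ChromosomeLocation"
    id: Optional[Curie] = Field(default=None, alias="_id")
    species_id: Curie
    chr: str
    interval: CytobandInterval

    @field_validator("chr")
    @classmethod
    def _chr(cls, v: str) -> str:
        if not v:
            raise ValueError("chr must be non-empty")
        if v.lower().startswith("chr"):
            raise ValueError("chr is stored without a 'chr' prefix")
        return v


Location = Union[SequenceLocation, ChromosomeLocation]


class LiteralSequenceExpression(_ValueObject):
    type: Literal["LiteralSequenceExpression"] = "LiteralSequenceExpression"
    sequence: SequenceString


class DerivedSequenceExpression(_ValueObject):
    type: Literal["DerivedSequenceExpression"] = "DerivedSequenceExpression"
    location: SequenceLocation
    reverse_complement: bool = False


class RepeatedSequenceExpression(_ValueObject):
    type: Literal["RepeatedSequenceExpression"] = "RepeatedSequenceExpression"
    seq_expr: Union[LiteralSequenceExpression, DerivedSequenceExpression] = Field(
        discriminator="type"
    )
    count: RangeOrNumber = Field(discriminator="type")

    @model_validator(mode="after")
    def _nonneg(self) -> "RepeatedSequenceExpression":
        c = self.count
        if isinstance(c, Number) and c.value < 0:
            raise ValueError("repeat count must be >= 0")
        if isinstance(c, DefiniteRange) and c.min < 0:
            raise ValueError("repeat count range must be >= 0")
        if isinstance(c, IndefiniteRange) and c.comparator == ">=" and c.value < 0:
            raise ValueError("repeat count bound must be >= 0")
        return self


SequenceExpression = Union[
    LiteralSequenceExpression, DerivedSequenceExpression, RepeatedSequenceExpression
]


class Gene(_ValueObject):
    type: Literal["Gene"] = "Gene"
    gene_id: Curie


class Allele(_ValueObject):
    """The state of a contiguous molecule at a Location."""

    type: Literal["Allele"] = "Allele"
    id: Optional[Curie] = Field(default=None, alias="_id")
    location: Union[SequenceLocation, ChromosomeLocation, Curie]
    state: SequenceExpression = Field(discriminator="type")


class Haplotype(_ValueObject):
    """A set of in-cis (phased) Alleles on one molecule."""

    type: Literal["Haplotype"] = "Haplotype"
    id: Optional[Curie] = Field(default=None, alias="_id")
    members: tuple[Union[Allele, Curie], ...] = Field(min_length=1)


class Text(_ValueObject):
    type: Literal["Text"] = "Text"
    id: Optional[Curie] = Field(default=None, alias="_id")
    definition: str

    @field_validator("definition")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("definition must be non-empty")
        return v


class CopyNumber(_ValueObject):
    """Systemic copy count of a molecular subject within a genome or cell."""

    type: Literal["CopyNumber"] = "CopyNumber"
    id: Optional[Curie] = Field(default=None, alias="_id")
    subject: Union[
        SequenceLocation,
        ChromosomeLocation,
        Gene,
        DerivedSequenceExpression,
        Curie,
    ]
    copies: RangeOrNumber = Field(discriminator="type")


class VariationSet(_ValueObject):
    type: Literal["VariationSet"] = "VariationSet"
    id: Optional[Curie] = Field(default=None, alias="_id")
    members: tuple[Union["Variation", Curie], ...] = ()


Variation = Union[Allele, Haplotype, Text, VariationSet, CopyNumber]

VariationSet.model_rebuild()


TYPE_REGISTRY: dict[str, type[_ValueObject]] = {
    cls.__name__: cls
    for cls in (
        Number,
        DefiniteRange,
        IndefiniteRange,
        SequenceInterval,
        CytobandInterval,
        SequenceLocation,
        ChromosomeLocation,
        LiteralSequenceExpression,
        DerivedSequenceExpression,
        RepeatedSequenceExpression,
        Allele,
        Haplotype,
        Text,
        VariationSet,
        CopyNumber,
        Gene,
    )
}

# Only Variation and Location subclasses are meaningful in isolation and
# therefore identifiable (plus raw Sequence strings, handled separately).
IDENTIFIABLE_TYPES = frozenset(
    {
        "Allele",
        "Haplotype",
        "Text",
        "VariationSet",
        "CopyNumber",
        "SequenceLocation",
        "ChromosomeLocation",
    }
)


def is_identifiable(type_name: str) -> bool:
    """Whether objects of this class may carry a computed identifier."""
    if type_name not in TYPE_REGISTRY:
        raise ValueError(f"unknown VRS type: {type_name!r}")
    return type_name in IDENTIFIABLE_TYPES


class MalformedDocumentError(ValueError):
    """The document is not a typed map (no 'type' discriminator)."""


@dataclass(frozen=True)
class Violation:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.path}: {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = field(default=())

    @property
    def ok(self) -> bool:
        return not self.violations


def _pydantic_violations(exc: ValidationError) -> list[Violation]:
    seen = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        v = Violation(path=path, message=err["msg"])
        if v not in seen:
            seen.append(v)
    return seen


def parse_object(document: Mapping[str, Any]) -> _ValueObject:
    """Construct the typed object a document describes, or raise."""
    if not isinstance(document, Mapping) or "type" not in document:
        raise MalformedDocumentError(
            "document has no 'type' discriminator field"
        )
    type_name = document["type"]
    if type_name not in TYPE_REGISTRY:
        raise ValueError(f"unknown VRS type: {type_name!r}")
    return TYPE_REGISTRY[type_name].model_validate(dict(document))


def _member_digests(obj: Union[Haplotype, VariationSet]) -> list[str]:
    from .identify import ga4gh_digest  # deferred: identify depends on models

    out = []
    for m in obj.members:
        out.append(m if isinstance(m, str) else ga4gh_digest(m))
    return out


def validate(document: Mapping[str, Any]) -> ValidationReport:
    """Structural validation of a parsed JSON-like document.

    Returns a report of zero or more violations; an empty report means the
    document constructs a valid typed object.  A document with no ``type``
    field at all is malformed rather than invalid and raises
    :class:`MalformedDocumentError`.
    """
    if not isinstance(document, Mapping) or "type" not in document:
        raise MalformedDocumentError("document has no 'type' discriminator field")
    type_name = document["type"]
    if type_name not in TYPE_REGISTRY:
        return ValidationReport(
            (Violation("type", f"unknown VRS type: {type_name!r}"),)
        )
    try:
        obj = TYPE_REGISTRY[type_name].model_validate(dict(document))
    except ValidationError as exc:
        return ValidationReport(tuple(_pydantic_violations(exc)))

    violations: list[Violation] = []
    # Sets and haplotypes are value objects: duplicate members carry no
    # meaning, detected via their computed digests.
    if isinstance(obj, (Haplotype, VariationSet)):
        digests = _member_digests(obj)
        if len(set(digests)) != len(digests):
            violations.append(
                Violation("members", "duplicate members after identification")
            )
    return ValidationReport(tuple(violations))
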