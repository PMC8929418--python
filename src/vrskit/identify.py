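"""Computed identifiers: digest, truncate, encode, prefix.

An identifier is minted in four steps: (1) normalize the object where rules
exist (Alleles), (2) digest-serialize it to canonical bytes, (3) hash with
SHA-512 truncated to 24 bytes and base64url-encode (``sha512t24u``), and
(4) assemble ``ga4gh:<type prefix>.<digest>``.  Because every step is a pure
function of the object's value, equal objects mint equal identifiers in any
process, on any machine, with no registry.

The 24-byte (192-bit) digest length is justified by the birthday bound: for a
corpus of m messages the collision probability is P = m^2 / 2^(b+1), so even
10^18 objects collide with probability below 10^-21.
"""

from __future__ import annotations

import base64
import hashlib
import math
from typing import Optional, Union

from .models import Allele, SequenceLocation, _ValueObject, is_identifiable
from .serialize import digest_serialize

__all__ = [
    "PREFIXES",
    "sha512t24u",
    "ga4gh_digest",
    "ga4gh_identify",
    "collision_probability",
    "min_digest_bits",
]

NAMESPACE = "ga4gh"

# Class-specific identifier prefixes; bijective by construction.
PREFIXES: dict[str, str] = {
    "Allele": "VA",
    "Text": "VT",
    "VariationSet": "VS",
    "Haplotype": "VH",
    "CopyNumber": "VCN",
    "SequenceLocation": "VSL",
    "ChromosomeLocation": "VCL",
    "Sequence": "SQ",
}


def sha512t24u(blob: bytes) -> str:
    """SHA-512 digest truncated to 24 bytes, base64url-encoded.

    24 bytes is divisible by 3, so the encoding is always exactly 32
    characters with no padding; this is enforced, not assumed.
    """
    digest = base64.urlsafe_b64encode(hashlib.sha512(blob).digest()[:24]).decode(
        "ascii"
    )
    assert len(digest) == 32 and "=" not in digest
    return digest


def ga4gh_digest(obj: Union[_ValueObject, str]) -> str:
    """Bare 32-character digest of an identifiable object or sequence."""
    return sha512t24u(digest_serialize(obj))


def _resolve_sequence_ids(obj: _ValueObject, store) -> _ValueObject:
    """Rewrite sequence_id aliases anywhere in the object to their ga4gh:SQ
    form via the store, so that synonymous accessions mint one identifier."""
    if isinstance(obj, SequenceLocation) and not obj.sequence_id.startswith(
        f"{NAMESPACE}:"
    ):
        sq = store.translate_sequence_identifier(obj.sequence_id, NAMESPACE)
        if not sq:
            raise ValueError(
                f"no ga4gh alias known for sequence {obj.sequence_id!r}"
            )
        return obj.model_copy(update={"sequence_id": sq[0]})
    updates = {}
    for name in type(obj).model_fields:
        value = getattr(obj, name)
        if isinstance(value, _ValueObject):
            resolved = _resolve_sequence_ids(value, store)
            if resolved is not value:
                updates[name] = resolved
        elif isinstance(value, tuple):
            resolved_items = tuple(
                _resolve_sequence_ids(v, store)
                if isinstance(v, _ValueObject)
                else v
                for v in value
            )
            if any(a is not b for a, b in zip(resolved_items, value)):
                updates[name] = resolved_items
    return obj.model_copy(update=updates) if updates else obj


def ga4gh_identify(
    obj: Union[_ValueObject, str],
    store=None,
    normalize: bool = True,
) -> str:
    """CURIE identifier ``ga4gh:<prefix>.<digest>`` for an identifiable
    object, or ``ga4gh:SQ.<digest>`` for a raw sequence string.

    When a sequence store is supplied, sequence accessions are first resolved
    to their ga4gh:SQ digests (synonym invariance) and, unless ``normalize``
    is disabled, literal Alleles are fully justified before digesting.
    Normalization is recommended rather than required: an Allele may also be
    read as an assertion of (possibly reference) state, which normalization
    would rewrite.
    """
    if isinstance(obj, str):
        return f"{NAMESPACE}:SQ.{sha512t24u(obj.upper().encode('utf-8'))}"
    type_name = type(obj).__name__
    if not is_identifiable(type_name):
        raise ValueError(f"{type_name} objects are not identifiable")
    if store is not None:
        if normalize and isinstance(obj, Allele):
            from .normalize import normalize_allele  # deferred: avoids cycle

            obj = normalize_allele(obj, store)
        obj = _resolve_sequence_ids(obj, store)
    return f"{NAMESPACE}:{PREFIXES[type_name]}.{ga4gh_digest(obj)}"


def collision_probability(m: float, b: int = 192) -> float:
    """Birthday-bound probability of any collision among ``m`` messages
    hashed to ``b`` bits: P = m^2 / 2^(b+1), clipped to [0, 1]."""
    if m < 0:
        raise ValueError("corpus size must be >= 0")
    if b <= 0:
        raise ValueError("digest length must be positive")
    if m == 0:
        return 0.0
    # work in log space to tolerate huge m and b
    log2_p = 2.0 * math.log2(float(m)) - (b + 1)
    if log2_p >= 0:
        return 1.0
    return 2.0 ** log2_p


def min_digest_bits(m: float, p: float) -> float:
    """Digest length b (bits) needed so that ``m`` messages collide with
    probability at most ``p``: b(m, P) = log2(m^2 / P) - 1."""
    if m < 1:
        raise ValueError("corpus size must be >= 1")
    if not (0 < p <= 1):
        raise ValueError("collision probability must be in (0, 1]")
    return 2.0 * math.log2(float(m)) - math.log2(p) - 1.0
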