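"""Sequence access behind the DataProxy contract.

A :class:`SequenceStore` holds reference sequences in memory, keyed by their
ga4gh:SQ digest, and maps external aliases (FASTA header tokens, accessions
from an alias table) onto those digests.  It exposes exactly the three
operations downstream code needs: slice a sequence, fetch its metadata, and
translate an identifier between namespaces.  All coordinates are
inter-residue; there are deliberately no residue-numbered entry points.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from Bio import SeqIO

from .identify import sha512t24u
from .models import SEQUENCE_PATTERN

__all__ = [
    "SequenceMetadata",
    "SequenceStore",
    "UnknownSequenceError",
    "CoordinateError",
    "load_fasta",
    "load_alias_table",
]


class UnknownSequenceError(KeyError):
    """Identifier does not resolve to any stored sequence."""


class CoordinateError(ValueError):
    """Inter-residue coordinates fall outside the sequence."""


@dataclass(frozen=True)
class SequenceMetadata:
    length: int
    alphabet: str
    aliases: tuple[str, ...]


class SequenceStore:
    """In-memory sequence repository implementing the DataProxy methods."""

    def __init__(self) -> None:
        self._sequences: dict[str, str] = {}  # SQ digest -> residues
        self._aliases: dict[str, str] = {}  # alias CURIE -> SQ digest

    # -- construction ----------------------------------------------------

    def add_sequence(self, sequence: str, aliases: Iterable[str] = ()) -> str:
        """Register a sequence; returns its ga4gh:SQ CURIE.

        The sequence is uppercase-folded before digesting so that case never
        splits identifiers.
        """
        sequence = sequence.upper()
        if not SEQUENCE_PATTERN.match(sequence):
            bad = sorted({c for c in sequence if not SEQUENCE_PATTERN.match(c)})
            raise ValueError(f"non-IUPAC characters in sequence: {bad}")
        digest = sha512t24u(sequence.encode("utf-8"))
        sq_curie = f"ga4gh:SQ.{digest}"
        self._sequences.setdefault(digest, sequence)
        self._aliases[sq_curie] = digest
        for alias in aliases:
            self.add_alias(alias, digest)
        return sq_curie

    def add_alias(self, alias: str, digest: str) -> None:
        if digest not in self._sequences:
            raise UnknownSequenceError(digest)
        existing = self._aliases.get(alias)
        if existing is not None and existing != digest:
            raise ValueError(f"alias {alias!r} already names a different sequence")
        self._aliases[alias] = digest

    def __len__(self) -> int:
        return len(self._sequences)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._aliases

    # -- DataProxy contract ----------------------------------------------

    def _resolve(self, identifier: str) -> str:
        try:
            return self._aliases[identifier]
        except KeyError:
            raise UnknownSequenceError(identifier) from None

    def get_sequence(
        self,
        identifier: str,
        start: Optional[int] = None,
        end: Optional[int] = None,
    ) -> str:
        """Residues between inter-residue positions ``start`` and ``end``."""
        seq = self._sequences[self._resolve(identifier)]
        if start is None and end is None:
            return seq
        start = 0 if start is None else start
        end = len(seq) if end is None else end
        if not (0 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"interval ({start}, {end}) out of bounds for length {len(seq)}"
            )
        return seq[start:end]

    def get_metadata(self, identifier: str) -> SequenceMetadata:
        digest = self._resolve(identifier)
        seq = self._sequences[digest]
        aliases = tuple(
            sorted(a for a, d in self._aliases.items() if d == digest)
        )
        return SequenceMetadata(
            length=len(seq),
            alphabet="".join(sorted(set(seq))),
            aliases=aliases,
        )

    def translate_sequence_identifier(
        self, identifier: str, namespace: str
    ) -> list[str]:
        """All aliases of the identified sequence in ``namespace``; an empty
        list (no alias there) is distinct from an unknown identifier, which
        raises."""
        digest = self._resolve(identifier)
        return sorted(
            a
            for a, d in self._aliases.items()
            if d == digest and a.split(":", 1)[0] == namespace
        )


def load_fasta(
    path: Union[str, os.PathLike, io.TextIOBase],
    namespace: str = "local",
    store: Optional[SequenceStore] = None,
) -> SequenceStore:
    """Build (or extend) a store from a FASTA file.

    Each record's header token becomes an alias ``<namespace>:<token>`` and
    its ga4gh:SQ identifier is precomputed from the raw residues.  Duplicate
    header tokens and non-IUPAC residues are errors.
    """
    store = store if store is not None else SequenceStore()
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        seen: set[str] = set()
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate FASTA header token: {record.id!r}")
            seen.add(record.id)
            alias = f"{namespace}:{record.id}"
            if alias in store:
                raise ValueError(f"duplicate alias: {alias!r}")
            store.add_sequence(str(record.seq), aliases=[alias])
    finally:
        if handle is not path:
            handle.close()
    return store


def load_alias_table(
    store: SequenceStore, path: Union[str, os.PathLike], namespace: str = "local"
) -> SequenceStore:
    """Attach external accessions from a two-column TSV
    (``alias CURIE <tab> local header token``) to stored sequences."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
            alias, token = parts
            digest = store._resolve(f"{namespace}:{token}")
            store.add_alias(alias, digest)
    return store
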