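"""Deterministic toy sequences and allele cases with controlled repeats.

Indel normalization is only interesting near repeats, so the generator
plants an exact repeat run (``motif`` x ``copies``) between random flanks
that are constrained not to extend the run, then derives substitution,
insertion, deletion and reference-match alleles on it.

Every generated case carries its expected normalized form, computed by a
brute-force *apply-and-compare* oracle that shares no code with the rolling
algorithm: it applies the edit, enumerates every single placement of the
same-length edit that reproduces the identical edited sequence, and takes
the union of those placements as the region of ambiguity.  Agreement between
the normalizer and this oracle is therefore evidence, not tautology.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import dataclasses
import json
import os
import random
from typing import Iterable, Optional, Union

from .models import (
    Allele,
    LiteralSequenceExpression,
    Number,
    SequenceInterval,
    SequenceLocation,
)
from .store import SequenceStore

__all__ = [
    "FixtureCase",
    "make_repeat_sequence",
    "make_indel_cases",
    "expected_normal_form",
    "apply_allele",
    "case_store",
    "write_corpus",
]

_ALPHABET = "ACGT"

TAGS = (
    "substitution",
    "insertion",
    "deletion",
    "reference",
    "homopolymer",
    "microsatellite",
)


@dataclasses.dataclass(frozen=True)
class FixtureCase:
    name: str
    sequence: str
    allele_in: Allele
    expected_interval: tuple[int, int]
    expected_state: str
    tags: tuple[str, ...]


def apply_allele(sequence: str, start: int, end: int, alt: str) -> str:
    """Edited sequence: replace the inter-residue span [start, end) by alt."""
    return sequence[:start] + alt + sequence[end:]


def _repeat_with_flanks(
    motif: str, copies: int, flank_len: int, rng: random.Random
) -> tuple[str, int]:
    """Sequence plus the planted run's start position.

    Boundary maximality (flanks never extend the run) always holds; whole-
    sequence uniqueness of the core is additionally sought by resampling,
    which succeeds except for very short cores inside long random flanks.
    """
    core = motif * copies
    if not core:
        return "".join(rng.choice(_ALPHABET) for _ in range(2 * flank_len)), flank_len
    fallback = None
    for _ in range(200):
        left = "".join(rng.choice(_ALPHABET) for _ in range(flank_len))
        right = "".join(rng.choice(_ALPHABET) for _ in range(flank_len))
        if left and left[-1] == motif[-1]:
            continue
        if right and right[0] == motif[0]:
            continue
        sequence = left + core + right
        if sequence.count(core) == 1:
            return sequence, flank_len
        if fallback is None:
            fallback = sequence
    if fallback is None:
        raise RuntimeError("could not place a maximal repeat run")
    return fallback, flank_len


def make_repeat_sequence(
    motif: str, copies: int, flank_len: int, seed: int
) -> str:
    """Random flanks around an exact ``motif * copies`` run.

    The left flank never ends with the motif's last base and the right flank
    never starts with its first base, so the planted run is maximal; for
    cores of a few bases or more it is also the unique occurrence.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if copies < 0 or flank_len < 0:
        raise ValueError("copies and flank_len must be >= 0")
    sequence, _ = _repeat_with_flanks(motif, copies, flank_len, random.Random(seed))
    return sequence


def expected_normal_form(
    sequence: str, start: int, end: int, alt: str
) -> tuple[int, int, str]:
    """Brute-force fully justified form of an edit, independent of rolling.

    Trims shared flanks by plain string comparison, then for an indel
    enumerates every placement of a same-length edit that yields the
    identical edited sequence and returns the union span with its alternate
    sequence.
    """
    ref = sequence[start:end]
    edited = apply_allele(sequence, start, end, alt)

    s, e, r, a = start, end, ref, alt
    while r and a and r[-1] == a[-1]:
        r, a, e = r[:-1], a[:-1], e - 1
    while r and a and r[0] == a[0]:
        r, a, s = r[1:], a[1:], s + 1

    if not r and not a:
        return start, end, alt  # reference match: unchanged
    if r and a:
        return s, e, a  # substitution (or delins)

    if not r:  # insertion of k characters
        k = len(a)
        placements = [
            p
            for p in range(len(sequence) + 1)
            if sequence[:p] + edited[p : p + k] + sequence[p:] == edited
        ]
        lo, hi = min(placements), max(placements)
        return lo, hi, edited[lo : hi + k]

    k = len(r)  # deletion of k characters
    placements = [
        p
        for p in range(len(sequence) - k + 1)
        if sequence[:p] + sequence[p + k :] == edited
    ]
    lo, hi = min(placements), max(placements)
    return lo, hi + k, edited[lo:hi]


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_ALPHABET) for _ in range(length))


def _case_allele(name: str, start: int, end: int, alt: str) -> Allele:
    return Allele(
        location=SequenceLocation(
            sequence_id=f"local:{name}",
            interval=SequenceInterval(
                start=Number(value=start), end=Number(value=end)
            ),
        ),
        state=LiteralSequenceExpression(sequence=alt),
    )


def make_indel_cases(n: int, seed: int) -> list[FixtureCase]:
    """``n`` seeded cases cycling through every tag.

    Motifs are 1-5 bp, copy numbers 1-8, flanks up to 20 bp and indels at
    most 10 bp, exercising homopolymers and microsatellites alongside plain
    substitutions and reference matches.  Expected values come from
    :func:`expected_normal_form` at generation time.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    cases: list[FixtureCase] = []
    for i in range(n):
        kind = TAGS[i % len(TAGS)]
        if kind == "homopolymer":
            motif_len = 1
            edit = rng.choice(("insertion", "deletion"))
        elif kind == "microsatellite":
            motif_len = rng.randint(2, 5)
            edit = rng.choice(("insertion", "deletion"))
        else:
            motif_len = rng.randint(1, 5)
            edit = kind
        motif = _random_sequence(rng, motif_len)
        copies = rng.randint(1, 8)
        flank_len = rng.randint(1, 20)
        sequence, run_start = _repeat_with_flanks(
            motif, copies, flank_len, random.Random(rng.randrange(2**31))
        )

        tags = [edit]
        if kind in ("homopolymer", "microsatellite"):
            tags.append(kind)

        if edit == "substitution":
            pos = rng.randrange(len(sequence))
            ref_base = sequence[pos]
            alt_base = rng.choice([b for b in _ALPHABET if b != ref_base])
            start, end, alt = pos, pos + 1, alt_base
        elif edit == "reference":
            start = rng.randrange(len(sequence))
            end = min(len(sequence), start + rng.randint(1, 5))
            alt = sequence[start:end]
        elif edit == "insertion":
            max_units = max(1, 10 // len(motif))
            units = rng.randint(1, max_units)
            # anchor somewhere on a motif boundary inside or beside the run
            offset = rng.randint(0, copies) * len(motif)
            start = end = run_start + offset
            alt = motif * units
        else:  # deletion
            max_units = max(1, min(copies, 10 // len(motif)))
            units = rng.randint(1, max_units)
            offset = rng.randint(0, copies - units) * len(motif)
            start = run_start + offset
            end = start + units * len(motif)
            alt = ""

        name = f"case{i:05d}"
        exp_start, exp_end, exp_state = expected_normal_form(
            sequence, start, end, alt
        )
        cases.append(
            FixtureCase(
                name=name,
                sequence=sequence,
                allele_in=_case_allele(name, start, end, alt),
                expected_interval=(exp_start, exp_end),
                expected_state=exp_state,
                tags=tuple(tags),
            )
        )
    return cases


def case_store(cases: Iterable[FixtureCase]) -> SequenceStore:
    """Store holding every case sequence under its ``local:<name>`` alias."""
    store = SequenceStore()
    for case in cases:
        store.add_sequence(case.sequence, aliases=[f"local:{case.name}"])
    return store


def write_corpus(
    cases: Iterable[FixtureCase],
    directory: Union[str, os.PathLike],
    basename: str = "corpus",
) -> tuple[str, str]:
    """Write cases as a conformance set: JSON Lines + companion FASTA."""
    os.makedirs(directory, exist_ok=True)
    fasta_path = os.path.join(directory, f"{basename}.fasta")
    jsonl_path = os.path.join(directory, f"{basename}.jsonl")
    with open(fasta_path, "w") as fasta:
        for case in cases:
            fasta.write(f">{case.name}\n")
            for i in range(0, len(case.sequence), 70):
                fasta.write(case.sequence[i : i + 70] + "\n")
    with open(jsonl_path, "w") as jsonl:
        for case in cases:
            jsonl.write(
                json.dumps(
                    {
                        "name": case.name,
                        "allele_in": case.allele_in.as_document(),
                        "expected_interval": list(case.expected_interval),
                        "expected_state": case.expected_state,
                        "tags": list(case.tags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    return fasta_path, jsonl_path
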