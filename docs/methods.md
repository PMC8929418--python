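# Methods

This note records the model implemented by vrskit, the numerical and design
choices that were genuinely open, what the synthetic fixtures emulate, and
the limits of what the tests show.

## Value-object model

All released VRS classes are implemented as frozen pydantic models with a
`type` discriminator on every document. The discriminator is required to
dispatch the polymorphic fields (`Allele.location`, `Allele.state`,
interval endpoints, `CopyNumber.subject`) without ambiguity. Equality and
hashing ignore the optional identifier slot, which is stored under the key
`_id` precisely so that the digest serializer's underscore filter removes
it without a special case. Sequence characters are uppercase-folded on
ingestion everywhere (model fields, FASTA records, raw digests): digests
are byte-sensitive, and mixed case would silently split identifiers.

Validation regexes are implementation-chosen where the specification
family only says that patterns exist:

- CURIE: `^\w[^:\s]*:\S+$` (namespace without colon, non-empty reference);
- cytoband designator: arm `p`/`q` plus dotted band numbers, with
  `pter`/`qter`/`cen` accepted;
- sequence strings: uppercase IUPAC plus `*` and `-`.

Haplotype/VariationSet member uniqueness is enforced at validation time
via member digests, because duplicates carry no meaning in a value object.

## Coordinates

All interfaces are strictly inter-residue: an interval `(a, b)` spans
`b − a` residues. No residue-numbered entry point exists anywhere except
inside the HGVS translator, which converts on parse (`residue n` →
`(n−1, n)`) and on format. This prevents the classic off-by-one class of
errors from mixing conventions.

## Normalization

The algorithm fully justifies literal alleles: trim the common suffix then
prefix; classify (reference match → returned untouched; substitution →
trimmed form); otherwise roll the surviving sequence left and right to find
the bounds of ambiguity and cover the whole region. Choices that the
written procedure leaves open, and how they were resolved:

- **Which copy of the allele sequence feeds the final state.** Rolling
  circularly permutes a *working copy* only; the final state is
  `context[left:start] + alt + context[end:right]` with the original,
  unpermuted alternate sequence. Feeding the permuted copy forward breaks
  edit preservation on repeat insertions, which the brute-force oracle
  catches immediately.
- **"Terminal base" in the two rolls.** The left roll compares the *last*
  character of the working copy against the base before the bound; the
  right roll compares the *first* character against the base after it.
  This is the only reading under which rolling reproduces the
  enumerate-all-placements region.
- **Deletions and the right roll.** Both rolls start at `start`. For a
  deletion the reference span equals the allele sequence, so the right
  roll consumes the deleted span itself before extending past it; the
  resulting bound is already the region's right edge. The final state
  formula above therefore uses `end` (not `start`) for the appended
  context, which keeps insertions and deletions in one code path.
- **Boundaries.** Rolling halts at position 0 and at the sequence length;
  there is no circular-genome wrap. Linear assemblies are the scope.
- **Character comparison** is exact byte equality. IUPAC ambiguity codes
  never match other codes (N does not roll against A); anything looser
  would make identifiers depend on an interpretation policy.
- **Shapes without rules.** Ranged coordinates, non-literal states and
  chromosome locations are returned unchanged with a
  `NotNormalizedWarning` — a soft signal, deliberately distinct from hard
  errors (unknown sequence, out-of-bounds interval). A reference-matching
  allele is also returned untouched: asserting reference state over a
  repetitive span is a legitimate intent that rewriting would destroy.
- Normalization is applied by default when minting identifiers but can be
  disabled per call (`normalize=False`), supporting the
  allele-as-assertion-of-state reading.

Context access during rolling goes through a lazy per-residue accessor, so
normalization touches only the located span plus the rolled neighbourhood —
it never needs the whole chromosome in memory.

## Digest serialization and identifiers

Canonical bytes are produced by `json.dumps(content, sort_keys=True,
separators=(",", ":"), ensure_ascii=False)` over the filtered content:
this yields UTF-8, no insignificant whitespace, keys in code-point order,
and two-character escapes where JSON defines them. All numeric fields in
the released classes are integers, so no float-canonicalization policy is
needed; it would have to be decided before any float field is ever added.
Nested identifiable objects and ga4gh CURIE references are reduced to bare
32-character digests; references outside the ga4gh namespace are an error
at serialization time (identification resolves aliases through the store
first, which is what makes synonym invariance hold). Only arrays of
digests/ids (set and haplotype members) are sorted; no other array-valued
field exists in the released classes.

`sha512t24u` truncates SHA-512 to 24 bytes and base64url-encodes; 24 is
divisible by 3, so the 32-character, padding-free form is enforced by
assertion rather than assumed. Collision analysis uses the birthday bound
`P = m²/2^(b+1)` and its inverse `b = log₂(m²/P) − 1`, computed in log
space so corpus sizes like 10¹⁸ lose no precision.

## Sequence store

An in-memory map from content digest to residues, with an alias index —
deliberately minimal. No network backend, no compressed or indexed access:
backend choice belongs to deployments, and the DataProxy surface
(`get_sequence`, `get_metadata`, `translate_sequence_identifier`) is the
contract anything larger would implement. FASTA headers become
`local:<token>` aliases, keeping toy fixtures CURIE-clean without claiming
real accessions; an optional two-column TSV attaches external accessions.
SQ digests are computed over uppercase-folded bytes (flagged: case
handling affects identifier equality with any implementation that folds
differently).

## Translators

SPDI positions are already inter-residue, so parsing is direct; a
sequence-form deletion field is checked against the store. The HGVS subset
is linear genomic-style (`g.`, `m.`, `n.`) substitution, del, ins, delins,
dup and identity, parsed with a regular grammar — the subset is regular,
so a parser generator would add machinery without adding coverage.
Transcript `c.` (UTR/intron offsets) and protein `p.` are out of scope.
Uncertain breakpoints (`(?_123)`) are rejected with a specific error
rather than approximated. `dup` maps to a molecular insertion of the
duplicated span immediately after it, never to a copy-number object:
tandem duplication is a statement about one molecule, and systemic claims
must be made explicitly with `CopyNumber`. Formatting to HGVS right-shifts
the fully justified allele (trim common prefix, then suffix) per the
3'-rule, emitting `dup` when the inserted bases equal the residues
immediately preceding the insertion point.

## Synthetic fixtures and the oracle

The generator plants an exact `motif × copies` run (motifs 1–5 bp, copies
1–8) between random flanks (up to 20 bp) constrained not to extend the
run, then derives substitutions, insertions, deletions (≤ 10 bp) and
reference matches on and around it — homopolymers and microsatellites are
the regimes where placement ambiguity actually occurs. Expected normalized
forms are computed at generation time by an independent oracle that shares
no rolling code: apply the edit, enumerate every placement of a
same-length edit reproducing the identical edited string, and take the
union span. Agreement between normalizer and oracle is therefore evidence.

What the fixtures do not emulate: real chromosome scale, IUPAC ambiguity
codes (rolling semantics for them are undefined, so the alphabet is ACGT),
interrupted or nested repeats beyond what random flanks produce, and real
accessions. Passing tests show the algorithms are correct on the repeat
structures that drive normalization; they do not benchmark performance on
genome-length sequences, although the lazy context accessor makes the cost
proportional to the rolled region, not the sequence.

Problem sizes used by the acceptance script — 1,000 oracle cases, 100
serialization shuffles, 100 translator round trips, 25 aliased contexts —
are large enough that every code path and tag occurs many times while the
whole script stays near-instant; the suite's percentages are computed, not
asserted.

## Known limitations

- No repeat-expression normalization (`RepeatedSequenceExpression` alleles
  are passed through with a warning); no haplotype- or copy-number-specific
  normalization rules exist to implement.
- No VCF translation; no transcript/protein HGVS; no ISCN.
- The store holds sequences in memory; multi-gigabase references belong
  behind a different DataProxy implementation.
- Cross-field constraints (interval start ≤ end) are enforced by the typed
  validator but are not expressible in the emitted schema dialect; the
  schema catches the per-field constraints (patterns, minima, required
  fields, enum tokens).
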