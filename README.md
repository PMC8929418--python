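# vrskit

A self-contained implementation of the GA4GH Variation Representation
Specification (VRS): immutable variation **value objects** on inter-residue
coordinates, **fully justified** allele normalization, canonical **digest
serialization**, globally consistent **computed identifiers**, and
translation to and from the HGVS and SPDI nomenclatures over a pluggable
sequence store.

## Who this is for

Anyone who needs to exchange or deduplicate molecular variation between
systems without pre-negotiating identifier namespaces: variant databases,
clinical reporting pipelines, knowledge bases. The same variant described
through synonymous accessions, or through different nomenclatures, resolves
to one identifier — computed locally, with no registry.

## The model in brief

- **Value objects.** An `Allele` is a `SequenceLocation` (a sequence
  identifier plus an inter-residue `SequenceInterval`) and a state (usually
  a `LiteralSequenceExpression`). Nothing else — no labels, no accessions,
  no annotations. Equality is content equality; objects are immutable.
- **Inter-residue coordinates.** An interval `(a, b)` counts the spaces
  between residues and spans `b − a` residues, so a location means the same
  thing for insertions, deletions and substitutions.
- **Full justification.** An indel in a repeat is ambiguous; rather than
  left- or right-aligning, normalization trims shared flanks, rolls the
  allele sequence through the repeat to find the bounds of ambiguity
  `[left, right)`, and returns an Allele covering the whole region with
  state `context[left:start] + alt + context[end:right]`.
- **Computed identifiers.** normalize → digest-serialize (canonical JSON,
  nested identifiable objects replaced by their digests, `_id`/null fields
  dropped, keys code-point ordered) → `sha512t24u` (SHA-512 truncated to 24
  bytes, base64url, 32 characters) → `ga4gh:<prefix>.<digest>` with a
  class prefix (`VA` Allele, `VSL` SequenceLocation, `SQ` sequence, ...).
  By the birthday bound `P = m²/2^(b+1)`, 10¹⁸ objects at 192 bits collide
  with probability below 10⁻²¹.

## Worked example

```python
import vrskit as vk

store = vk.SequenceStore()
store.add_sequence("TTACACACAGG", aliases=["local:rep1"])

raw = vk.parse_spdi("local:rep1:9:0:CA", store)   # CA inserted at position 9
normalized = vk.normalize_allele(raw, store)
iv = normalized.location.interval
print(iv.start.value, iv.end.value, normalized.state.sequence)
print(vk.format_hgvs(normalized, store))
print(vk.ga4gh_identify(raw, store=store))
```

prints

```
2 9 ACACACACA
local:rep1:g.8_9dup
ga4gh:VA.03salJbPVbBSzTHI26nHXehF7L1KGpIE
```

The CA insertion is ambiguous anywhere in the CA-repeat (residues 3–9);
the normalized Allele covers the entire region `(2, 9)` and replaces the
run `ACACACA` with `ACACACACA` — one added unit, no falsely precise
position. HGVS renders the same event 3'-shifted as a duplication, and
both forms mint the identical `ga4gh:VA.` identifier.

More narrative scripts live in `examples/` (value objects and
identification, normalization vs. a brute-force oracle, HGVS/SPDI
convergence, sequence stores and aliases, collision analysis); each runs
standalone with `python examples/<name>.py`.

## Command line

```sh
vrskit seq-digest ref.fasta
vrskit validate objects.jsonl
echo 'local:tiny1:g.2C>T' | vrskit translate --from hgvs --to spdi --fasta ref.fasta -
vrskit identify --fasta ref.fasta alleles.jsonl
```

All commands stream JSON Lines; per-record errors go to stderr as JSON
without aborting the batch.

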