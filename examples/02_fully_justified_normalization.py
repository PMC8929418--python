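"""Fully justify an ambiguous repeat insertion.

Inserting "CA" into the CA-repeat of TTACACACAGG is possible at many
equivalent positions.  Instead of picking one arbitrarily (left- or
right-aligning), normalization returns an Allele covering the entire
region of ambiguity.
"""

import vrskit as vk

SEQ = "TTACACACAGG"
store = vk.SequenceStore()
store.add_sequence(SEQ, aliases=["local:rep1"])

# a CA insertion at inter-residue position 9 (3' edge of the repeat)
raw = vk.parse_spdi("local:rep1:9:0:CA", store)
normalized = vk.normalize_allele(raw, store)

iv = normalized.location.interval
print("input interval:  (9, 9)  state: CA")
print(
    f"normalized:      ({iv.start.value}, {iv.end.value})"
    f"  state: {normalized.state.sequence}"
)

# the rolled bounds match a brute-force enumeration of every equivalent
# placement of the same insertion
expected = vk.expected_normal_form(SEQ, 9, 9, "CA")
print("oracle agrees: ", (iv.start.value, iv.end.value, normalized.state.sequence) == expected)

# both forms describe the same edited molecule
edited_raw = vk.apply_allele(SEQ, 9, 9, "CA")
edited_norm = vk.apply_allele(SEQ, iv.start.value, iv.end.value, normalized.state.sequence)
print("edit preserved:", edited_raw == edited_norm, "->", edited_norm)

# The normalized interval (2, 9) with state ACACACACA says: the CA run of
# residues 3-9 becomes ACACACACA — one extra CA unit, located over the whole
# run rather than at a falsely precise point.
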