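"""Translate between HGVS, SPDI and the value-object form.

Different nomenclatures describe the same repeat insertion differently
(HGVS right-shifts to a dup, SPDI left-anchors) — but both parse to the
same fully justified value and therefore the same computed identifier.
"""

import vrskit as vk

store = vk.SequenceStore()
store.add_sequence("TTACACACAGG", aliases=["local:rep1"])
store.add_sequence("CCTAC", aliases=["local:tiny1"])

# a substitution, through both nomenclatures
sub_hgvs = vk.parse_hgvs("local:tiny1:g.2C>T", store)
sub_spdi = vk.parse_spdi("local:tiny1:1:1:T", store)
print("substitution converges:", sub_hgvs == sub_spdi)
print("  hgvs:", vk.format_hgvs(sub_spdi, store))
print("  spdi:", vk.format_spdi(sub_spdi, store))

# a repeat insertion: HGVS dup vs SPDI
ins = vk.parse_spdi("local:rep1:9:0:CA", store)
normalized = vk.normalize_allele(ins, store)
hgvs = vk.format_hgvs(normalized, store)
spdi = vk.format_spdi(normalized, store)
print("repeat insertion renders as")
print("  hgvs:", hgvs, " (3'-shifted dup)")
print("  spdi:", spdi, " (fully justified span)")

id_hgvs = vk.ga4gh_identify(vk.parse_hgvs(hgvs, store), store=store)
id_spdi = vk.ga4gh_identify(vk.parse_spdi(spdi, store), store=store)
print("one identifier for both:", id_hgvs == id_spdi)
print(" ", id_hgvs)
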