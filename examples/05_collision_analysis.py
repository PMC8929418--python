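"""Why a 24-byte truncated digest is enough.

The birthday bound P = m^2 / 2^(b+1) gives the probability of any collision
among m messages hashed to b bits; inverting it gives the digest length
needed for a target probability.
"""

import vrskit as vk

m = 10**18  # a generous corpus: a billion billion variation objects
p = vk.collision_probability(m, 192)
print(f"P(collision | m=1e18, b=192 bits) = {p:.3g}")
print("below 1e-21:", p < 1e-21)

bits = vk.min_digest_bits(m, 1e-21)
print(f"bits needed for P<1e-21 at m=1e18: {bits:.2f} (24 bytes = 192)")

# and the digest really is 24 bytes / 32 base64url characters:
digest = vk.sha512t24u(b"ACGT")
print("sha512t24u('ACGT') =", digest, f"({len(digest)} chars)")
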