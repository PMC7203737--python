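"""Build an ADM from an IUPAC seed and inspect its elementary properties.

Run: python examples/01_adm_basics.py
"""

import numpy as np

from admotif import (
    consensus,
    marginals,
    reverse_complement,
    seed_to_adm,
    seq_probability,
)

# An order-zero starting model for the HOXB13-like seed: allowed bases at
# each position share 80% of the probability.
adm = seed_to_adm("CYMRTAAAA", match_weight=0.8)

print(f"length: {adm.length}")
print(f"consensus (highest-probability site): {consensus(adm)}")
print(f"P(consensus) = {seq_probability(adm, consensus(adm)):.3e}")
print(f"P(CTCGTAAAA) = {seq_probability(adm, 'CTCGTAAAA'):.3e}")

m = marginals(adm)
print("\nper-position marginals (rows = positions, cols = A C G T):")
print(np.round(m, 3))

rc = reverse_complement(adm)
print(f"\nreverse-complement consensus: {consensus(rc)}")
s = "CCAATAAAA"
print(
    f"P_rc(revcomp({s})) == P({s}): "
    f"{np.isclose(seq_probability(rc, 'TTTTATTGG'), seq_probability(adm, s))}"
)
# The two probabilities agree exactly: reverse complementing an
# order-one chain is exact, not an approximation.
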