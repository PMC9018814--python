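"""Test for the 2:1 co-ortholog signature of whole-genome duplication.

After a WGD in the focal lineage, every reference-species gene should
have exactly two focal co-orthologs.  The fraction of reference genes
showing that pattern distinguishes a duplicated from an unduplicated
family.
"""

from v2rscan.classification import test_wgd_ratio
from v2rscan.simulate import simulate_wgd_family

dup = simulate_wgd_family(10, focal="teleost", reference="gar",
                          duplicated=True, seed=8)
frac, hist = test_wgd_ratio(dup, "teleost", "gar")
print(f"post-WGD family:   2:1 fraction = {frac:.2f}  histogram = {hist}")

single = simulate_wgd_family(10, focal="teleost", reference="gar",
                             duplicated=False, seed=8)
frac0, hist0 = test_wgd_ratio(single, "teleost", "gar")
print(f"no-duplication:    2:1 fraction = {frac0:.2f}  histogram = {hist0}")
print("(a fraction near 1 is the WGD signature; near 0 rules it out)")
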