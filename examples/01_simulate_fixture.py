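"""Generate the standard synthetic study and write it to disk.

Two species, ~1 Mb of genome each, 15 receptor genes per species laid
out like a real V2R repertoire: f-V2Rs inside a landmark-flanked
cluster, the single-copy V2R2/ancV2R genes in tandem next to PLC eta1,
t-V2Rs dispersed on a second scaffold, and 20% of the expanded-clade
genes decayed into pseudogenes.
"""

import collections
import tempfile

from v2rscan.fixtures import default_fixture
from v2rscan.simulate import write_fixture

fam = default_fixture(seed=20)

counts = collections.Counter(
    (r.species, r.clade) for r in fam.truth_records if r.status != "landmark"
)
print("planted genes per species and clade:")
for (sp, clade), n in sorted(counts.items()):
    print(f"  {sp:6s} {clade:8s} {n}")

status = collections.Counter(
    r.status for r in fam.truth_records if r.status != "landmark"
)
print(f"status mix: {dict(status)}  (stop/frameshift/truncated are pseudogenes)")

outdir = tempfile.mkdtemp(prefix="v2r_fixture_")
paths = write_fixture(
    list(fam.genomes.values()), fam.truth_records, fam.species_tree, outdir
)
print("fixture written:")
for key, path in paths.items():
    print(f"  {key:12s} {path}")
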