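"""Delimit the landmark-flanked receptor cluster and report gene order.

The f-V2R cluster sits between PLC eta1 and neprilysin; V2R2 and ancV2R
are in tandem next to PLC eta1; t-V2Rs live on other scaffolds.  The
report reproduces that arrangement from coordinates alone.
"""

from v2rscan import synteny as sy
from v2rscan.fixtures import default_fixture

fam = default_fixture(seed=20)

loci = sy.loci_from_truth(fam.truth_records)
clade_of = {r.gene_id: r.clade for r in fam.truth_records
            if r.status != "landmark"}
clusters = sy.delimit_clusters(loci)
genes = [l for l in loci if l.name_class == "v2r"]
labels, table = sy.classify_by_cluster(genes, clusters, clade_of)

print(f"{len(clusters)} landmark-flanked cluster(s) found")
print("\nclade x in/out-of-cluster contingency:")
print(table.to_string())

report = sy.cluster_report(clusters, loci, clade_of)
for cl in report:
    print(f"\ncluster {cl['scaffold']}:{cl['interval'][0]}-{cl['interval'][1]}"
          f"  (V2R2/ancV2R tandem next to PLC: {cl['v2r2_ancv2r_tandem']})")
    for e in cl["entries"]:
        print(f"  {e['start']:>8} {e['strand']} {e['label']:20s} {e['gene_id']}")
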