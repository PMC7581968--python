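"""Enumerate connection classes from a module partition.

Builds the default study-layout parcellation (360 cortical + 19 subcortical
regions, 4 planted modules per hemisphere) and lists every connection class
the partition implies. With 4 left and 4 right modules the classification
yields 16 interhemispheric + 12 intrahemispheric + 8 intramodular +
8 subcortical-cortical = 44 classes — the number of connection-level tests
the group contrast later corrects across.
"""

import connectotype as ct

parcellation = ct.make_parcellation(ct.GeneratorConfig(seed=0))
partition = ct.planted_partition(parcellation)
classes = ct.enumerate_connection_classes(partition, parcellation)

print(f"parcellation: {parcellation.n_regions} regions "
      f"({len(parcellation.cortical_ids)} cortical, "
      f"{len(parcellation.subcortical_ids)} subcortical)")
counts = {}
for c in classes:
    counts[c.kind] = counts.get(c.kind, 0) + 1
for kind, n in counts.items():
    print(f"  {kind:22s} {n:3d} classes")
print(f"  {'total':22s} {len(classes):3d} classes")
print("first three class labels:", [c.label for c in classes[:3]])
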