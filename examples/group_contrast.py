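"""Connection-type group contrast on a synthetic cohort.

Simulates the three-group study (34 controls, 67 PD high visual performers,
33 PD low visual performers) with a 20% interhemispheric and 10%
subcortical-cortical attenuation planted in the low performers, then runs
the analysis chain: summed class strengths, per-class linear model
(group + age + sex) with BH-FDR across the 44 classes, tanh WM-loss
scores, and the composite interhemispheric loss. Significant classes
should appear only in the attenuated connection types.
"""

import connectotype as ct

cohort = ct.make_cohort(ct.GeneratorConfig(seed=7))
classes = ct.enumerate_connection_classes(cohort.partition, cohort.parcellation)
strengths, meta = ct.cohort_class_strengths(cohort.connectomes, classes)

result = ct.contrast_classes(strengths, meta, groups=("pd_high", "pd_low"))
print("significant classes (q < 0.05) per connection type:")
for kind, sub in result.groupby("kind"):
    print(f"  {kind:22s} {int(sub['significant'].sum()):2d} / {len(sub)}")

loss = ct.wm_loss(strengths, meta)
composite = ct.composite_loss(loss.loss, "interhemispheric")
for group in ("control", "pd_high", "pd_low"):
    vals = composite[meta["group"] == group]
    print(f"composite interhemispheric loss, {group:8s}: "
          f"mean {vals.mean():+.3f}")

means, edges = ct.class_lengths(cohort.lengths, classes,
                                weights=cohort.connectomes[0].weights)
kind_mean = means.groupby(means.index.map(lambda s: s.split(':')[0])).mean()
print("mean connection length (mm) by type:")
print(kind_mean.round(1).to_string())
print("(higher composite loss in pd_low than pd_high reflects the planted "
      "attenuation; long-range connection types are the vulnerable ones)")
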