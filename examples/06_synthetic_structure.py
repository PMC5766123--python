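"""Synthetic structured datasets: planted groups through the full pipeline.

Generates a two-island dataset (groups five mutation steps apart, spatially
clustered), shows that GST falls as migration-like admixture rises, and
that the SAMOVA search recovers the planted partition.
"""

from haplogeo.diversity import pons_petit
from haplogeo.simulate import GeneratorConfig, generate
from haplogeo.structure import AnnealingSchedule, samova

print("GST under increasing admixture (two planted groups):")
for mix in (0.0, 0.2, 0.4, 0.8):
    cfg = GeneratorConfig(n_populations=10, n_groups=2, between_group_steps=5,
                          haplotype_freq_concentration=5.0, admixture=mix,
                          seed=17)
    part = pons_petit(generate(cfg))
    print(f"  admixture={mix:.1f}: GST={part.GST:.3f} NST={part.NST:.3f}")

ds = generate(GeneratorConfig(n_populations=8, n_groups=2,
                              between_group_steps=5, seed=5))
res = samova(ds, K=2, schedule=AnnealingSchedule(8, 2000), seed=0)
print("\nSAMOVA recovery of the planted two-island structure:")
for pop in ds.populations:
    print(f"  {pop.label}: group {res.groups[pop.label]}")
print(f"  F_CT = {res.F_CT:.3f}")
print("\nDifferentiation estimates track the planted mixing level, and the")
print("annealing search splits the islands cleanly.")
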