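"""Coverage factors, dendrite statistics, and the geometry scale model.

How redundantly do cholinergic arbor territories tile the mouse cortex
and hippocampus?  And what does a single neuron look like when every
linear dimension is blown up 10,000-fold?
"""

from arbormetry import (
    CoverageInputs,
    GeometryModel,
    coverage_factor,
    dendrite_population_stats,
    neuron_geometry,
    scale_model,
)

for n in (4_500, 6_632):
    inputs = CoverageInputs(
        n_neurons=n,
        mean_arbor_volume_mm3=1.35,  # mean P30 arbor territory, polygon method
        target_volume_mm3=130.0,  # cortex (109) + hippocampus (21)
        mean_dendrite_volume_mm3=0.0694,
        mean_dendrite_length_mm=11.5,
        dendrite_territory_volume_mm3=0.667,  # basal forebrain nuclei
    )
    cov = coverage_factor(inputs)
    dcov, ddens = dendrite_population_stats(inputs)
    print(
        f"n = {n}: axon coverage {cov:.0f}x, dendrite coverage {dcov:.0f}x, "
        f"dendrite density {ddens:.3f} um/um^3"
    )

model = GeometryModel()  # rat values: 0.3 um axon, 30 um soma, 62 cm arbor
g = neuron_geometry(model)
print(f"\naxon volume:        {g.axon_volume_per_m_um3 / 1e3:.1f} x 10^3 um^3 per m")
print(f"varicosity volume:  {g.varicosity_volume_per_m_um3 / 1e3:.1f} x 10^3 um^3 per m")
print(f"soma volume:        {g.soma_volume_um3 / 1e3:.1f} x 10^3 um^3")
print(f"volume ratio:       {g.volume_ratio:.1f} (neurites vs soma)")
print(f"surface ratio:      {g.surface_ratio:.0f} (axon vs soma)")

print("\nscale model at 10^4:")
for name, (value, unit) in scale_model(model, factor=1e4).items():
    print(f"  {name}: {value:g} {unit}")
# Despite 62 cm of cable, the arbor adds only ~4x the soma's volume --
# but >200x its surface area, a membrane-maintenance burden made vivid
# by the scale model: a 30 cm soma trailing 6.2 km of 3 mm cable.
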