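"""Cross-species per-neuron axon length estimates.

Applies the density, total-length, and varicosity estimator routes to
the shipped table of published population inputs and prints each
computed mean axon length next to the value the literature reports.
"""

from arbormetry import estimate_axon_lengths

df = estimate_axon_lengths()
cols = ["label", "route", "computed_value", "computed_unit", "printed_value", "printed_unit"]
print(df[cols].to_string(index=False))
# Density route: (axon density x target volume) / neuron count.
# Human forebrain cholinergic neurons come out at ~107 m of axon each --
# three orders of magnitude beyond the ~31 cm of their mouse counterparts.
# The dopaminergic varicosity row computes 49-68 cm from its own printed
# inputs although the source prints 55-77 cm; both values are retained.
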