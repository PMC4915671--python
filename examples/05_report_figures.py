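"""Reporting: topographic significance maps, RMS bars and vector plots.

Reruns the channel-wise MANOVA of the previous example and renders the
three figure styles; every figure gets a CSV twin holding exactly the
numbers drawn.
"""

import matplotlib

matplotlib.use("Agg")

import flowssvep as fs
from flowssvep.report import rms_bar_plot, significance_map, top_channels, vector_plot

spec = fs.StimulusSpec()
cm = fs.hydrocel_like_layout()
topo = fs.demo_topography(cm)
comp = fs.simulate_subject_components(
    fs.StudyDesign(n_subjects=29), topo, spec, seed=6, harmonics=("1F1",),
)

res = fs.mass_univariate(comp, "1F1")
fig, df = significance_map(res.table, cm, out="scratch_map_1f1")
marked = df[df.most_stringent_alpha.notna()]
print(f"significance map: {marked.channel.nunique()} channels marked across "
      f"{df.effect.nunique()} effect panels -> scratch_map_1f1.svg/.csv")

best = top_channels(comp, "1F1", k=9)
print(f"nine highest-amplitude channels at 1F1: {best.tolist()} "
      "(ranked by across-participant mean RMS amplitude)")

fig, bars = rms_bar_plot(comp, "1F1", best, by="pattern", out="scratch_bars_1f1")
peak = bars.loc[bars["mean"].idxmax()]
print(f"largest mean RMS amplitude: {peak['mean']:.2f} uV "
      f"(channel {int(peak.channel)}, {peak.pattern}) -> scratch_bars_1f1.svg/.csv")

fig, vec = vector_plot(comp, "1F1", best, by="pattern", out="scratch_vectors_1f1")
print("vector plots: mean (re, im) per pattern with separate SEM bars "
      "-> scratch_vectors_1f1.svg/.csv; amplitude = distance from origin, "
      "phase = angle")
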