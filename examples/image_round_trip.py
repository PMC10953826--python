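"""Render a simulated well, segment it, and compare with the ground truth.

Builds one well with a ~50/50 duct/cluster mix and 30% dead organoids,
renders the two-channel image, runs the full imaging pass (segment ->
features -> classify -> viability), and scores the result against the
generator's truth table. Count error and the two accuracies show how
faithfully the rule-based classifier recovers the designed well contents.
"""

from admscreen import (
    analyze_well_image,
    render_well_image,
    roundtrip_metrics,
    simulate_well_objects,
)
from admscreen.simgen import CompoundRecord, WellSpec

record = CompoundRecord("MIX-1", "balanced mix", "other",
                        cluster_shift_inh=40.0, cytotox_frac=0.3)
spec = WellSpec("P1", 0, 0, "MIX-1", 1.0, "inhibition", 0)

truth = simulate_well_objects(spec, record, rng_seed=7)
image = render_well_image(truth, rng_seed=7)
labels, objects = analyze_well_image(image)

n_ducts = sum(o.predicted_class == "duct" for o in objects)
print(f"truth: {truth.n_objects} organoids "
      f"({(truth.objects['true_class'] == 'duct').sum()} ducts), "
      f"{int(truth.objects['true_live'].sum())} live")
print(f"imaging: {len(objects)} objects ({n_ducts} ducts), "
      f"{sum(bool(o.live) for o in objects)} live")

m = roundtrip_metrics([(truth, objects)])
print(f"count error {m.count_error:.1%}, class accuracy "
      f"{m.class_accuracy:.1%}, viability accuracy {m.live_accuracy:.1%}")
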