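# admscreen

Analytics for a morphology-based organoid drug screen targeting pancreatic
**acinar-to-ductal metaplasia (ADM)** — the transdifferentiation of acinar
cells into duct-like cells that is among the earliest events on the road to
pancreatic ductal adenocarcinoma. In the assay this package models, mouse
acinar organoids in 384-well plates either form duct-like structures
(inhibition mode: can a compound prevent ADM?) or have already formed them
(reversal mode: can a compound turn ducts back into acinar clusters?).
Wells are imaged in a morphology channel plus a green calcein-AM viability
channel; the readout is the percentage of live duct-like vs live
cluster-like organoids among all live objects.

The package covers the full analysis chain, with a synthetic-data generator
standing in for the raw microscopy and qPCR data so every stage is testable
end to end:

- **simgen** – deterministic 144-compound epigenetic library fixture with
  ground-truth effects, object-level well simulation (~50 organoids/well),
  two-channel 16-bit image rendering, qPCR CT tables and DE tables.
- **imaging** – segmentation of organoids from the morphology channel, shape
  features (area, Crofton form factor, solidity, eccentricity, lumen ratio),
  transparent duct/cluster classification, per-object viability calls.
- **screenstats** – per-well summaries, Welch's unequal-variance t-test, the
  Z'-factor plate QC, and three-criterion hit selection:
  (i) more live clusters than vehicle at p ≤ 0.05, (ii) more total clusters
  at p ≤ 0.05, (iii) ≤ 50% cytotoxicity.
- **doseresp** – four-parameter logistic fits,
  `y = bottom + (top − bottom)/(1 + (x/IC50)^hill)`, by variable projection
  with multi-start, reporting IC50 in dose units.
- **molindex** – relative qPCR quantification (2^−ΔΔCT, 18S-normalized,
  vehicle-referenced) and the **ADM Reversal Index**

  ```
  ADMRI = mean FC(Amy2a, Cela1, Cpa2) / mean FC(Krt19, Krt7, Sox9)
  ```

  with dense per-dose ranking, plus volcano-style annotation of DE tables
  against a packaged 27-acinar / 23-ductal-PDAC gene panel.

## Worked example

```python
from admscreen import generate_library_fixture, run_screen

library = generate_library_fixture()          # 144 compounds
result = run_screen(library, mode="reversal", seed=1)
name_of = {r.compound_id: r.name for r in library}
print(f"Z' = {result.qc.z_prime:.3f}")
print(sorted(name_of[c] for c in result.hit_ids()))
```

prints

```
Z' = 0.648
['apicidin', 'chaetocin']
```

The Z' of 0.65 (vehicle ≈ 5% live clusters, positive control ≈ 89%) says
the simulated reversal plate separates its controls well enough for
screening (> 0.5). The two hits are the compounds whose designed effects
raise the live-cluster percentage without exceeding 50% cytotoxicity; the
designed cytotoxic active tubastatin A passes both morphology criteria but
is rejected by the viability gate. In inhibition mode the same call
recovers apicidin and chaetocin from six significant actives, four of which
are excluded as cytotoxic. Because hit calling uses raw p ≤ 0.05 across
144 compounds (no multiplicity correction), a screen realization typically
also contains a few false-positive hits among the inert compounds — see
`docs/methods.md`.

More narrative walkthroughs live in `examples/` (screens, imaging round
trip, IC50 fitting, ADMRI ranking, volcano annotation); each prints the
numbers it computes and a line on what they mean. A thin CLI mirrors the
library (`admscreen screen --mode inhibition --seed 1 --out out/`,
`admscreen demo`, `admscreen admri`, …).

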