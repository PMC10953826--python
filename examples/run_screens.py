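"""Run both simulated 144-compound screens and print the hit structure.

Simulates every well at the object level (no images), applies the
three-criterion hit selection against each plate's vehicle wells, and
reports the Z' plate quality plus which designed compounds survive each
gate. Expect the two prioritized compounds (apicidin, chaetocin) as hits in
both modes, with the strongly cytotoxic actives excluded by the viability
gate — plus occasionally a stray false positive among the 137 inert
compounds, which is exactly what raw p <= 0.05 across a library predicts.
"""

from admscreen import generate_library_fixture, run_screen

library = generate_library_fixture()
name_of = {r.compound_id: r.name for r in library}

for mode in ("inhibition", "reversal"):
    result = run_screen(library, mode=mode, seed=1)
    designed = {r.compound_id for r in library if r.shift_for(mode) > 0}
    significant = {h.compound_id for h in result.hits if h.pass_i}
    excluded = {h.compound_id for h in result.hits
                if h.pass_i and h.pass_ii and not h.pass_iii}
    hits = result.hit_ids()
    print(f"== {mode} screen ==")
    print(f"  plate QC: Z' = {result.qc.z_prime:.3f} "
          f"(vehicle {result.qc.mu_neg:.1f}%, control {result.qc.mu_pos:.1f}%"
          " live clusters)")
    print(f"  designed actives significant (criterion i): "
          f"{sorted(name_of[c] for c in designed & significant)}")
    print(f"  excluded by >50% cytotoxicity (criterion iii): "
          f"{sorted(name_of[c] for c in excluded)}")
    print(f"  final hits: {sorted(name_of[c] for c in hits)}")
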