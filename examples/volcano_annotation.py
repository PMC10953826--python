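"""Annotate a simulated differential-expression table with the gene panel.

Simulates a bulk-expression reversal signature (acinar genes up, ductal/PDAC
genes down, 1000 inert background genes), then labels each gene against the
packaged 27-acinar / 23-ductal panel using the |FC| > 1.5 and FDR < 0.05
cuts. The concordance is the fraction of panel genes moving in the direction
the reversal signature predicts.
"""

from admscreen import annotate_volcano, default_gene_panel, simulate_de_table

panel = default_gene_panel()
de = simulate_de_table(panel, reversal_strength=2.5,
                       n_background_genes=1000, rng_seed=4)
annotated, summary = annotate_volcano(de, panel)

print(f"{summary['n_genes']} genes; panel {summary['panel_size']} "
      f"(27 acinar + 23 ductal/PDAC)")
print(f"acinar up-significant:  {summary['acinar_up_significant']}/27")
print(f"ductal down-significant: {summary['ductal_down_significant']}/23")
print(f"reversal concordance: {summary['concordance']:.2f}")
background_sig = annotated[(annotated["gene_set"] == "background")
                           & (annotated["significance"] != "ns")]
print(f"background genes passing the cuts: {len(background_sig)}")
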