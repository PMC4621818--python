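"""Ordinal drought scoring, leaf relative water content, cross-year correlations.

The three visual 0-5 scales are whole-plant wilting (Wt), unifoliate
senescence (Scu, from the senesced leaf-area fraction) and stem greenness
(Stg).  Scores from a simulated 95-accession panel are correlated across
trait-year combinations; non-significant cells are masked, as such tables
are conventionally printed.
"""

from drylysim import phenotypes, synth

print("Scu index by senesced leaf area:")
for f in (0.0, 0.15, 0.5, 0.75, 0.95):
    print(f"  {f:>4.0%} senesced -> score {phenotypes.scu_score(f)}")
print(f"  dead/fallen      -> score {phenotypes.scu_score(0.3, dead_or_fallen=True)}")

rwc = phenotypes.rwc(phenotypes.RwcInput(fw=7, dw=2, tw=10))
print(f"\nLeaf RWC for FW=7 g, DW=2 g, TW=10 g: {rwc:.1f}%")

panel = synth.simulate_panel(
    truth=synth.PanelTruth(
        causal_snps={"Scu": [(10, 1.0)], "Wt": [(200, 1.0)], "Stg": [(400, 1.0)]},
        h2={"Scu": 0.5, "Wt": 0.4, "Stg": 0.5},
    ),
    seed=1,
)
r, p = phenotypes.trait_correlations(panel.scores)
print("\nCross-year trait correlations (NaN = not significant at P <= 0.05):")
print(r.round(3).to_string())
print("\nSame-trait columns across years correlate when heritability is "
      "nonzero; pure-noise pairs are mostly masked.")
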