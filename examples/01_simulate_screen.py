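"""Simulate a full 9-plate, 1059-compound morphology screen.

Generates the per-well feature table (median colony area, percent
colonies with lumens, colony count, texture-like extras) with plate
effects, positional gradients, 6 planted hit compounds and 20 cytotoxic
compounds, plus the ground truth of what was planted.
"""

from morphoscreen import example_screen_config, simulate_screen

config = example_screen_config(seed=1, n_hit_compounds=6, n_dead_compounds=20)
features, truth = simulate_screen(config)

df = features.data
print(f"wells: {len(df)} on {df['plate_id'].nunique()} plates")
print(df["role"].value_counts().to_string())
print(f"planted hit wells: {len(truth.hit_wells)} "
      f"({len({h['compound_id'] for h in truth.hit_wells})} compounds)")
print(f"planted cytotoxic wells: {len(truth.dead_wells)}")
print("\nfirst rows:")
print(df.head(4).to_string(index=False))
# Each row is one well; DMSO wells define the untreated (spiky) baseline,
# positive wells carry the re-epithelializing control effect, and hit
# compounds multiply median area ~3x and shift the lumen fraction +0.4.
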