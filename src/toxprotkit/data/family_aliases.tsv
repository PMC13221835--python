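# Cross-year family renames: normalized name -> canonical 2025-era name.
# Seeded from documented renames/consolidations.
Snake toxin family	Snake three-finger toxin family
Huwentoxin-1 family	Neurotoxin 10 (Hwtx-1) family
Spider toxin Tx3 family	Neurotoxin 10 (Hwtx-1) family
Spider potassium channel inhibitory toxin family	Neurotoxin 10 (Hwtx-1) family
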