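# Order-level habitat seed. Orders spanning both habitats are "mixed" and
# fall through to the genus-level table.
Araneae	terrestrial
Anura	terrestrial
Batrachoidiformes	marine
Blenniiformes	marine
Hemiptera	terrestrial
Hymenoptera	terrestrial
Lepidoptera	terrestrial
Myliobatiformes	mixed
Nectiopoda	marine
Neogastropoda	marine
Phyllodocida	marine
Scolopendromorpha	terrestrial
Scorpiones	terrestrial
Squamata	mixed
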