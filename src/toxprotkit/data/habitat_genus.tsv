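# Genus-level overrides for mixed-habitat orders. Includes the documented
# edge cases: the estuarine-coastal snake Cerberus and the river stingray
# Potamotrygon are grouped marine; the freshwater snake Pseudoferania is
# grouped terrestrial.
Aipysurus	marine
Cerberus	marine
Crotalus	terrestrial
Emydocephalus	marine
Hydrophis	marine
Laticauda	marine
Naja	terrestrial
Potamotrygon	marine
Pseudoferania	terrestrial
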