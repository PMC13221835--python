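----------------------------------------------------------------------------
        Curated seed of a modified-residue controlled vocabulary in the
        ptmlist record format (ID = modified-residue description,
        KW = standardized biological category). This is a synthetic seed
        covering the descriptions the fixture generator emits; extend or
        replace with a full ptmlist-format file for real data.
----------------------------------------------------------------------------
ID   Alanine amide
KW   Amidation
//
ID   Arginine amide
KW   Amidation
//
ID   Asparagine amide
KW   Amidation
//
ID   Aspartate amide
KW   Amidation
//
ID   Cysteine amide
KW   Amidation
//
ID   Glutamate amide
KW   Amidation
//
ID   Glutamine amide
KW   Amidation
//
ID   Glycine amide
KW   Amidation
//
ID   Histidine amide
KW   Amidation
//
ID   Isoleucine amide
KW   Amidation
//
ID   Leucine amide
KW   Amidation
//
ID   Lysine amide
KW   Amidation
//
ID   Methionine amide
KW   Amidation
//
ID   Phenylalanine amide
KW   Amidation
//
ID   Proline amide
KW   Amidation
//
ID   Serine amide
KW   Amidation
//
ID   Threonine amide
KW   Amidation
//
ID   Tryptophan amide
KW   Amidation
//
ID   Tyrosine amide
KW   Amidation
//
ID   Valine amide
KW   Amidation
//
ID   4-hydroxyproline
KW   Hydroxylation
//
ID   3-hydroxyproline
KW   Hydroxylation
//
ID   4-hydroxylysine
KW   Hydroxylation
//
ID   5-hydroxylysine
KW   Hydroxylation
//
ID   (3R)-3-hydroxyasparagine
KW   Hydroxylation
//
ID   Pyrrolidone carboxylic acid
KW   Pyrrolidone carboxylic acid
//
ID   4-carboxyglutamate
KW   Gamma-carboxyglutamic acid
//
ID   D-serine
KW   D-amino acid
//
ID   Bromohistidine
KW   Halogenation
//
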