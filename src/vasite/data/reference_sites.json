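{
  "comment": "Curated residue sets lining known tubulin drug, nucleotide and zinc binding pockets, for overlap reporting against predicted anesthetic sites. Residues are written as <a|b><one-letter code><number> with 'a' = alpha-tubulin, 'b' = beta-tubulin; numbering follows the standard electron-crystallographic tubulin scheme. These are inputs, not code.",
  "sets": {
    "taxol": ["bV23", "bD26", "bL217", "bL219", "bH229", "bL230", "bA233", "bS236",
              "bF272", "bP274", "bL275", "bT276", "bS277", "bR278",
              "bP360", "bR369", "bQ370", "bL371"],
    "colchicine": ["bC241", "bD251", "bV318", "bK352", "aE71", "aN101", "aV181"],
    "vinblastine": ["aL248", "aN249", "aL352", "bV177", "bD179", "bY210", "bF214"],
    "peloruside_a": ["bQ294", "bD297", "bR308", "bV335", "bN339", "bY342"],
    "laulimalide": ["bF296", "bR308", "bV335", "bN339", "bY342"],
    "gtp_n_site": ["aG10", "aQ11", "aA12", "aQ15", "aI16", "aD69", "aL70", "aE71",
                   "aV74", "aA99", "aA100", "aN101", "aS140", "aF141", "aG142",
                   "aG143", "aG144", "aT145", "aG146", "aI171", "aY172", "aP173",
                   "aA174", "aT179", "aA180", "aE183", "aN206", "aY224", "aL227",
                   "aN228", "aI231", "bL248", "bN249", "bK254", "bK352"],
    "gtp_e_site": ["bG10", "bQ11", "bC12", "bQ15", "bI16", "bD69", "bL70", "bE71",
                   "bT74", "bA99", "bG100", "bN101", "bS140", "bL141", "bG142",
                   "bG143", "bG144", "bT145", "bG146", "bV171", "bV172", "bP173",
                   "bS174", "bD179", "bT180", "bE183", "bN206", "bY224", "bL227",
                   "bN228", "bV231", "aL248", "aN249", "aE254", "aK352"],
    "zinc_sheet_formation": ["aH192", "aE420", "aD424"],
    "zinc_alpha_uncharacterized": ["aH266", "aD431"],
    "zinc_near_colchicine": ["bC243", "bC356", "bD357"]
  }
}
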