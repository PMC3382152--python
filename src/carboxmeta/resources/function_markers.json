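{
  "_comment": "Illustrative default marker sets for the ten fermentation-related function flags reported for taxonomic bins. Each function id maps to a list of alternative KEGG-orthology marker sets: a flag is raised when ALL terms of ANY one alternative set are present in a bin. These defaults are editable, plausible choices (e.g. acetate production keyed to acetate kinase plus phosphotransacetylase) and are NOT an authoritative pathway reconstruction; supply your own map for real analyses.",
  "functions": {
    "1": {"label": "Cellulose degradation", "marker_sets": [["K01179"], ["K19668"]]},
    "2": {"label": "Cellobiose uptake and/or degradation", "marker_sets": [["K02761"], ["K01223"], ["K05350"]]},
    "3": {"label": "Xylan/xylose uptake and/or degradation", "marker_sets": [["K01181"], ["K01805"]]},
    "4": {"label": "Arabinose uptake and/or degradation", "marker_sets": [["K01804"], ["K01209"]]},
    "5": {"label": "Multiple sugar transporters", "marker_sets": [["K02025", "K02026"]]},
    "6": {"label": "Acetate production", "marker_sets": [["K00925", "K00625"]]},
    "7": {"label": "Ethanol production", "marker_sets": [["K00001"], ["K04072"]]},
    "8": {"label": "Propanoate production", "marker_sets": [["K01026"], ["K00932"]]},
    "9": {"label": "Butanoate production", "marker_sets": [["K00634", "K00929"], ["K00248"]]},
    "10": {"label": "Potential valerate/caproate production", "marker_sets": [["K00248", "K03522", "K03521"]]}
  }
}
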