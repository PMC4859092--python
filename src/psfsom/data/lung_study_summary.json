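{
  "description": "Published scale of the lung-disease pathway activity study: pathway collection size before and after curation, and the total number of pathway sink nodes scored per sample.",
  "n_kegg_pathways_initial": 291,
  "n_pathways_selected": 138,
  "n_sinks_total": 943
}
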