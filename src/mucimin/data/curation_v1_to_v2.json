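[
 {
  "kind": "remove_reaction",
  "payload": "R_GLMS",
  "rationale": "No GlmS homologue is encoded in the genome; the Fru6P + glutamine -> GlcN6P + glutamate amination (EC 2.6.1.16) was a gap-filling artefact and the purified NagB candidate shows no glutamine-dependent activity.",
  "new_metabolites": []
 }
]
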