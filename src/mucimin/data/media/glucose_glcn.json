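{
 "name": "glucose_glcn",
 "sugar_budget": 10.0,
 "components": [
  {
   "metabolite": "thr_e",
   "category": "limited_uptake",
   "bound": 1.0
  },
  {
   "metabolite": "gln_e",
   "category": "non_limiting",
   "bound": null
  },
  {
   "metabolite": "h2o_e",
   "category": "non_limiting",
   "bound": null
  },
  {
   "metabolite": "glc_e",
   "category": "sugar",
   "bound": null
  },
  {
   "metabolite": "glcn_e",
   "category": "sugar",
   "bound": null
  }
 ]
}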