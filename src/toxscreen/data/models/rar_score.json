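{
 "model_name": "RAR_score",
 "slices": [
  {
   "slice_name": "RAR",
   "assay_ids": [
    "RARA_1",
    "RARB_1",
    "RARG_1",
    "RARE_1"
   ]
  }
 ]
}
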