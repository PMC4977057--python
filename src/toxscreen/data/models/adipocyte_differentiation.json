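{
 "model_name": "adipocyte_differentiation",
 "slices": [
  {
   "slice_name": "PPARg",
   "assay_ids": [
    "PPARG_1",
    "PPARG_2",
    "PPARG_3",
    "PPARG_4",
    "PPRE_1"
   ]
  },
  {
   "slice_name": "RXRA",
   "assay_ids": [
    "RXRA_1"
   ]
  },
  {
   "slice_name": "GR",
   "assay_ids": [
    "NR3C1_1",
    "NR3C1_2",
    "NR3C1_3",
    "NR3C1_4"
   ]
  },
  {
   "slice_name": "LXR",
   "assay_ids": [
    "NR1H2_1",
    "NR1H3_1",
    "LXRE_1"
   ]
  },
  {
   "slice_name": "Other",
   "assay_ids": [
    "CEBPB_1",
    "SREBF1_1"
   ]
  }
 ]
}
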