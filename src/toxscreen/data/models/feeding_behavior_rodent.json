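{
 "model_name": "feeding_behavior_rodent",
 "slices": [
  {
   "slice_name": "CCK",
   "assay_ids": [
    "CCKAR_1",
    "CCKBR_1"
   ]
  },
  {
   "slice_name": "ESR1",
   "assay_ids": [
    "ESR1_1",
    "ESR1_2",
    "ESR1_3",
    "ESR1_4"
   ]
  },
  {
   "slice_name": "ESRRA",
   "assay_ids": [
    "ESRRA_1"
   ]
  },
  {
   "slice_name": "FoxO1",
   "assay_ids": [
    "FOXO1_1"
   ]
  },
  {
   "slice_name": "IL6",
   "assay_ids": [
    "IL6_1"
   ]
  },
  {
   "slice_name": "INSR",
   "assay_ids": [
    "INSR_1",
    "INSR_2"
   ]
  },
  {
   "slice_name": "MAP",
   "assay_ids": [
    "MAPK3_1",
    "MAPK3_2",
    "MAPK3_3"
   ]
  },
  {
   "slice_name": "NPY",
   "assay_ids": [
    "NPY1R_1",
    "NPY2R_1",
    "NPY5R_1"
   ]
  },
  {
   "slice_name": "STAT3",
   "assay_ids": [
    "STAT3_1"
   ]
  }
 ]
}
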