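{
 "model_name": "feeding_behavior_celegans",
 "slices": [
  {
   "slice_name": "DRD2",
   "assay_ids": [
    "DRD2_1"
   ]
  },
  {
   "slice_name": "GSK3B",
   "assay_ids": [
    "GSK3B_1"
   ]
  },
  {
   "slice_name": "HTR2C",
   "assay_ids": [
    "HTR2C_1"
   ]
  },
  {
   "slice_name": "HTR3A",
   "assay_ids": [
    "HTR3A_1"
   ]
  },
  {
   "slice_name": "HTR2A",
   "assay_ids": [
    "HTR2A_1"
   ]
  },
  {
   "slice_name": "OtherHTR",
   "assay_ids": [
    "SLC6A4_1",
    "SLC6A4_2",
    "HTR1A_1",
    "HTR4_1",
    "HTR6_1",
    "HTR7_1",
    "HTR5A_1"
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
   "slice_name": "NPY",
   "assay_ids": [
    "NPY1R_1",
    "NPY2R_1",
    "NPY5R_1"
   ]
  },
  {
   "slice_name": "PPARd",
   "assay_ids": [
    "PPARD_1"
   ]
  },
  {
   "slice_name": "PRKACA",
   "assay_ids": [
    "PRKACA_1"
   ]
  },
  {
   "slice_name": "Sstr1",
   "assay_ids": [
    "SSTR1_1"
   ]
  },
  {
   "slice_name": "Other",
   "assay_ids": [
    "PPARG_1",
    "PPARG_2",
    "PPARG_3",
    "PPARG_4",
    "PPRE_1",
    "DRD4_1",
    "DRD1_1",
    "NR1I1_1",
    "NR1I1_2",
    "NR1H2_1",
    "NR1H3_1",
    "NR1H3_2",
    "CEBPB_1"
   ]
  }
 ]
}
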