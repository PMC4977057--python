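{
 "model_name": "beta_cell_function",
 "slices": [
  {
   "slice_name": "ACHE",
   "assay_ids": [
    "ACHE_1",
    "ACHE_2"
   ]
  },
  {
   "slice_name": "BCHE",
   "assay_ids": [
    "BCHE_1"
   ]
  },
  {
   "slice_name": "DRD",
   "assay_ids": [
    "DRD1_1",
    "DRD2_1",
    "DRD3_1",
    "DRD5_1",
    "OPRD1_1"
   ]
  },
  {
   "slice_name": "DRD_slc",
   "assay_ids": [
    "SLC6A3_1",
    "SLC6A3_2"
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
   "slice_name": "GABA",
   "assay_ids": [
    "GABR_1",
    "GABR_2",
    "GABR_3",
    "GABR_4",
    "GABR_5"
   ]
  },
  {
   "slice_name": "HTR",
   "assay_ids": [
    "HTR2A_1",
    "HTR2C_1",
    "HTR3A_1",
    "HTR1A_1",
    "HTR4_1",
    "HTR6_1",
    "HTR7_1",
    "HTR5A_1"
   ]
  },
  {
   "slice_name": "HTR_slc",
   "assay_ids": [
    "SLC6A4_1",
    "SLC6A4_2"
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
   "slice_name": "Kcnj11",
   "assay_ids": [
    "KCNJ11_1"
   ]
  },
  {
   "slice_name": "PPARa",
   "assay_ids": [
    "PPARA_1",
    "PPARA_2"
   ]
  },
  {
   "slice_name": "PPARd",
   "assay_ids": [
    "PPARD_1"
   ]
  },
  {
   "slice_name": "PPARg",
   "assay_ids": [
    "PPARG_1",
    "PPARG_2",
    "PPARG_3",
    "PPARG_4"
   ]
  },
  {
   "slice_name": "PPRE",
   "assay_ids": [
    "PPRE_1"
   ]
  }
 ]
}
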