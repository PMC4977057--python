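{
 "model_name": "insulin_sensitivity",
 "slices": [
  {
   "slice_name": "AKT",
   "assay_ids": [
    "AKT1_1",
    "AKT1_2"
   ]
  },
  {
   "slice_name": "CREB",
   "assay_ids": [
    "CREB3_1"
   ]
  },
  {
   "slice_name": "FOX",
   "assay_ids": [
    "FOXA2_1",
    "FOXO1_1"
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
  },
  {
   "slice_name": "PTPN1",
   "assay_ids": [
    "PTPN1_1"
   ]
  },
  {
   "slice_name": "SREBF1",
   "assay_ids": [
    "SREBF1_1"
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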