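{
 "model_name": "islet_cell_function",
 "slices": [
  {
   "slice_name": "betaCatenin",
   "assay_ids": [
    "TCF_CTNNB_1"
   ]
  },
  {
   "slice_name": "DRD1",
   "assay_ids": [
    "DRD_bt_1"
   ]
  },
  {
   "slice_name": "FOXA2",
   "assay_ids": [
    "FOXA2_1"
   ]
  },
  {
   "slice_name": "FOXO1",
   "assay_ids": [
    "FOXO1_1"
   ]
  },
  {
   "slice_name": "GSK3B",
   "assay_ids": [
    "GSK3B_1"
   ]
  },
  {
   "slice_name": "HNF4A",
   "assay_ids": [
    "HNF4A_1"
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
   "slice_name": "ONECUT1",
   "assay_ids": [
    "ONECUT1_1"
   ]
  },
  {
   "slice_name": "PAX6",
   "assay_ids": [
    "PAX6_1"
   ]
  },
  {
   "slice_name": "PTPN1",
   "assay_ids": [
    "PTPN1_1"
   ]
  }
 ]
}
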