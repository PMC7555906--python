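{
 "name": "table6",
 "comment": "Final validation set of 13 blind samples (12/13 fully correct, 92%).",
 "samples": [
  {
   "sample_id": "15 S",
   "truth": "human_blood",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "human",
    "level_iii": "n/a",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "22 S",
   "truth": "human_blood",
   "enhancement": "AY-7",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "human",
    "level_iii": "n/a",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "104 F",
   "truth": "chicken_blood",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "chicken",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "121 F",
   "truth": "saliva",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "no",
    "level_ii": "n/a",
    "level_iii": "n/a",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "127 F",
   "truth": "semen",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "no",
    "level_ii": "n/a",
    "level_iii": "n/a",
    "level_iv": "semen"
   }
  },
  {
   "sample_id": "128 F",
   "truth": "bovine_blood",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "bovine",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "129 F",
   "truth": "chicken_blood",
   "enhancement": "AY-7",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "chicken",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "138 F",
   "truth": "bovine_blood",
   "enhancement": "AY-7",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "inconclusive",
    "level_iv": "none-detected"
   },
   "marker_overrides": {
    "mammal-gapdh-1764": "absent",
    "bovine-myoglobin-1670": "absent"
   },
   "comment": "myoglobin marker at nominal 1593 detected without the GAPDH marker at 1764; correctly claimed animal blood but species inconclusive"
  },
  {
   "sample_id": "146 F",
   "truth": "non_biofluid",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "no",
    "level_ii": "n/a",
    "level_iii": "n/a",
    "level_iv": "none-detected"
   },
   "comment": "beet juice"
  },
  {
   "sample_id": "147 F",
   "truth": "semen",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "no",
    "level_ii": "n/a",
    "level_iii": "n/a",
    "level_iv": "semen"
   }
  },
  {
   "sample_id": "155 F",
   "truth": "porcine_blood",
   "enhancement": "AY-7",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "porcine",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "156 F",
   "truth": "porcine_blood",
   "enhancement": "none",
   "expected_claim": {
    "level_i": "yes",
    "level_ii": "animal",
    "level_iii": "porcine",
    "level_iv": "none-detected"
   }
  },
  {
   "sample_id": "176 F",
   "truth": "semen",
   "enhancement": "AY-7",
   "expected_claim": {
    "level_i": "no",
    "level_ii": "n/a",
    "level_iii": "n/a",
    "level_iv": "semen"
   },
   "comment": "presumptive test indicated blood; correctly identified as semen"
  }
 ],
 "subsets": {
  "animal": [
   "104 F",
   "128 F",
   "129 F",
   "138 F",
   "155 F",
   "156 F"
  ]
 }
}
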