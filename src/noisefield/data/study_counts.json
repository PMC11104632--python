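{
 "version": 1,
 "description": "Per-group/per-stage agreement outcome counts for both noise conditions, the number of eyes detected by both, and the ease-of-recognition preference tally among those eyes.",
 "groups": {
  "normal": {
   "n": 35,
   "cg": {"agreement": 0, "partial_agreement": 0, "no_agreement": 1, "no_response": 34},
   "analog": {"agreement": 0, "partial_agreement": 0, "no_agreement": 0, "no_response": 35}
  },
  "ppg": {
   "n": 19,
   "cg": {"agreement": 0, "partial_agreement": 0, "no_agreement": 0, "no_response": 19},
   "analog": {"agreement": 0, "partial_agreement": 0, "no_agreement": 0, "no_response": 19}
  }
 },
 "glaucoma": {
  "M1": {
   "n": 97,
   "cg": {"agreement": 45, "partial_agreement": 21, "no_agreement": 0, "no_response": 31},
   "analog": {"agreement": 35, "partial_agreement": 14, "no_agreement": 0, "no_response": 48},
   "both_detected": 49,
   "preference": {"cg": 37, "same": 10, "analog": 2}
  },
  "M2": {
   "n": 55,
   "cg": {"agreement": 38, "partial_agreement": 13, "no_agreement": 0, "no_response": 4},
   "analog": {"agreement": 32, "partial_agreement": 12, "no_agreement": 0, "no_response": 11},
   "both_detected": 44,
   "preference": {"cg": 29, "same": 10, "analog": 5}
  },
  "M3": {
   "n": 33,
   "cg": {"agreement": 17, "partial_agreement": 14, "no_agreement": 0, "no_response": 2},
   "analog": {"agreement": 15, "partial_agreement": 11, "no_agreement": 0, "no_response": 7},
   "both_detected": 26,
   "preference": {"cg": 19, "same": 5, "analog": 2}
  },
  "M4": {
   "n": 20,
   "cg": {"agreement": 16, "partial_agreement": 1, "no_agreement": 0, "no_response": 3},
   "analog": {"agreement": 14, "partial_agreement": 1, "no_agreement": 0, "no_response": 5},
   "both_detected": 15,
   "preference": {"cg": 9, "same": 5, "analog": 1}
  }
 }
}
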