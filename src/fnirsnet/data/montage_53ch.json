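{
 "nominal_distance_mm": 30.0,
 "sources": {
  "S1": [
   0.0,
   -0.0,
   0.0
  ],
  "S2": [
   60.0,
   -0.0,
   0.0
  ],
  "S3": [
   120.0,
   -0.0,
   0.0
  ],
  "S4": [
   180.0,
   -0.0,
   0.0
  ],
  "S5": [
   0.0,
   -17.32050807568877,
   0.0
  ],
  "S6": [
   60.0,
   -17.32050807568877,
   0.0
  ],
  "S7": [
   120.0,
   -17.32050807568877,
   0.0
  ],
  "S8": [
   180.0,
   -17.32050807568877,
   0.0
  ],
  "S9": [
   0.0,
   -34.64101615137754,
   0.0
  ],
  "S10": [
   60.0,
   -34.64101615137754,
   0.0
  ],
  "S11": [
   120.0,
   -34.64101615137754,
   0.0
  ],
  "S12": [
   180.0,
   -34.64101615137754,
   0.0
  ],
  "S13": [
   0.0,
   -51.96152422706631,
   0.0
  ],
  "S14": [
   60.0,
   -51.96152422706631,
   0.0
  ],
  "S15": [
   120.0,
   -51.96152422706631,
   0.0
  ],
  "S16": [
   180.0,
   -51.96152422706631,
   0.0
  ]
 },
 "detectors": {
  "D1": [
   30.0,
   -0.0,
   0.0
  ],
  "D2": [
   90.0,
   -0.0,
   0.0
  ],
  "D3": [
   150.0,
   -0.0,
   0.0
  ],
  "D4": [
   210.0,
   -0.0,
   0.0
  ],
  "D5": [
   30.0,
   -17.32050807568877,
   0.0
  ],
  "D6": [
   90.0,
   -17.32050807568877,
   0.0
  ],
  "D7": [
   150.0,
   -17.32050807568877,
   0.0
  ],
  "D8": [
   210.0,
   -17.32050807568877,
   0.0
  ],
  "D9": [
   30.0,
   -34.64101615137754,
   0.0
  ],
  "D10": [
   90.0,
   -34.64101615137754,
   0.0
  ],
  "D11": [
   150.0,
   -34.64101615137754,
   0.0
  ],
  "D12": [
   210.0,
   -34.64101615137754,
   0.0
  ],
  "D13": [
   30.0,
   -51.96152422706631,
   0.0
  ],
  "D14": [
   90.0,
   -51.96152422706631,
   0.0
  ],
  "D15": [
   150.0,
   -51.96152422706631,
   0.0
  ],
  "D16": [
   210.0,
   -51.96152422706631,
   0.0
  ]
 },
 "channels": [
  {
   "index": 1,
   "source": "S1",
   "detector": "D1"
  },
  {
   "index": 2,
   "source": "S1",
   "detector": "D5"
  },
  {
   "index": 3,
   "source": "S5",
   "detector": "D1"
  },
  {
   "index": 4,
   "source": "S5",
   "detector": "D5"
  },
  {
   "index": 5,
   "source": "S5",
   "detector": "D9"
  },
  {
   "index": 6,
   "source": "S9",
   "detector": "D9"
  },
  {
   "index": 7,
   "source": "S9",
   "detector": "D13"
  },
  {
   "index": 8,
   "source": "S13",
   "detector": "D13"
  },
  {
   "index": 9,
   "source": "S2",
   "detector": "D1"
  },
  {
   "index": 10,
   "source": "S6",
   "detector": "D1"
  },
  {
   "index": 11,
   "source": "S2",
   "detector": "D5"
  },
  {
   "index": 12,
   "source": "S6",
   "detector": "D5"
  },
  {
   "index": 13,
   "source": "S10",
   "detector": "D5"
  },
  {
   "index": 14,
   "source": "S10",
   "detector": "D9"
  },
  {
   "index": 15,
   "source": "S14",
   "detector": "D9"
  },
  {
   "index": 16,
   "source": "S14",
   "detector": "D13"
  },
  {
   "index": 17,
   "source": "S2",
   "detector": "D2"
  },
  {
   "index": 18,
   "source": "S2",
   "detector": "D6"
  },
  {
   "index": 19,
   "source": "S6",
   "detector": "D2"
  },
  {
   "index": 20,
   "source": "S6",
   "detector": "D6"
  },
  {
   "index": 21,
   "source": "S6",
   "detector": "D10"
  },
  {
   "index": 22,
   "source": "S10",
   "detector": "D10"
  },
  {
   "index": 23,
   "source": "S10",
   "detector": "D14"
  },
  {
   "index": 24,
   "source": "S14",
   "detector": "D14"
  },
  {
   "index": 25,
   "source": "S3",
   "detector": "D2"
  },
  {
   "index": 26,
   "source": "S7",
   "detector": "D2"
  },
  {
   "index": 27,
   "source": "S3",
   "detector": "D6"
  },
  {
   "index": 28,
   "source": "S7",
   "detector": "D6"
  },
  {
   "index": 29,
   "source": "S11",
   "detector": "D6"
  },
  {
   "index": 30,
   "source": "S11",
   "detector": "D10"
  },
  {
   "index": 31,
   "source": "S15",
   "detector": "D10"
  },
  {
   "index": 32,
   "source": "S15",
   "detector": "D14"
  },
  {
   "index": 33,
   "source": "S3",
   "detector": "D3"
  },
  {
   "index": 34,
   "source": "S3",
   "detector": "D7"
  },
  {
   "index": 35,
   "source": "S7",
   "detector": "D7"
  },
  {
   "index": 36,
   "source": "S7",
   "detector": "D11"
  },
  {
   "index": 37,
   "source": "S11",
   "detector": "D11"
  },
  {
   "index": 38,
   "source": "S11",
   "detector": "D15"
  },
  {
   "index": 39,
   "source": "S15",
   "detector": "D15"
  },
  {
   "index": 40,
   "source": "S4",
   "detector": "D3"
  },
  {
   "index": 41,
   "source": "S8",
   "detector": "D3"
  },
  {
   "index": 42,
   "source": "S8",
   "detector": "D7"
  },
  {
   "index": 43,
   "source": "S12",
   "detector": "D7"
  },
  {
   "index": 44,
   "source": "S12",
   "detector": "D11"
  },
  {
   "index": 45,
   "source": "S16",
   "detector": "D11"
  },
  {
   "index": 46,
   "source": "S16",
   "detector": "D15"
  },
  {
   "index": 47,
   "source": "S4",
   "detector": "D4"
  },
  {
   "index": 48,
   "source": "S4",
   "detector": "D8"
  },
  {
   "index": 49,
   "source": "S8",
   "detector": "D8"
  },
  {
   "index": 50,
   "source": "S8",
   "detector": "D12"
  },
  {
   "index": 51,
   "source": "S12",
   "detector": "D12"
  },
  {
   "index": 52,
   "source": "S12",
   "detector": "D16"
  },
  {
   "index": 53,
   "source": "S16",
   "detector": "D16"
  }
 ],
 "reference_points": {
  "Nz": [
   105.0,
   40.0,
   -30.0
  ],
  "Cz": [
   105.0,
   -160.0,
   60.0
  ],
  "AL": [
   -40.0,
   -60.0,
   -40.0
  ],
  "RL": [
   250.0,
   -60.0,
   -40.0
  ]
 }
}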