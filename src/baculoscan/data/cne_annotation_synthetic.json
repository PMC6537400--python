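{
 "clusters": {
  "C1": [
   3,
   14
  ],
  "C2": [
   20,
   31
  ],
  "C3": [
   40,
   51
  ],
  "C4": [
   66,
   77
  ],
  "C5": [
   86,
   97
  ],
  "C6": [
   110,
   121
  ],
  "C7": [
   135,
   146
  ]
 },
 "dyads": {
  "DSl": {
   "span": [
    10,
    55
   ],
   "ir": [
    [
     12,
     23
    ],
    [
     44,
     55
    ]
   ]
  },
  "DSc": {
   "span": [
    60,
    100
   ],
   "ir": [
    [
     62,
     72
    ],
    [
     90,
     100
    ]
   ]
  },
  "DSr": {
   "span": [
    105,
    150
   ],
   "ir": [
    [
     107,
     118
    ],
    [
     139,
     150
    ]
   ]
  }
 },
 "note": "synthetic stand-in annotation; C1-C7 cluster spans and DS/IR architecture constructed to mirror the canonical alphabaculovirus CNE layout"
}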