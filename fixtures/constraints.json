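{
 "n_transactions": 33,
 "universe": [
  "BL13",
  "BL17",
  "BL18",
  "BL20",
  "BL21",
  "BL23",
  "DU14",
  "DU20",
  "DU26",
  "GB20",
  "GB34",
  "HT7",
  "KI3",
  "LI10",
  "LI11",
  "LI4",
  "LR3",
  "PC5",
  "PC6",
  "RN10",
  "RN12",
  "RN13",
  "RN4",
  "RN6",
  "RN8",
  "SJ5",
  "SJ6",
  "SP10",
  "SP3",
  "SP6",
  "SP9",
  "ST19",
  "ST21",
  "ST25",
  "ST36",
  "ST37",
  "ST39",
  "ST40"
 ],
 "constraints": [
  {
   "items": [
    "DU20"
   ],
   "count": 9,
   "kind": "exact"
  },
  {
   "items": [
    "DU20",
    "RN12"
   ],
   "count": 9,
   "kind": "exact"
  },
  {
   "items": [
    "HT7"
   ],
   "count": 9,
   "kind": "exact"
  },
  {
   "items": [
    "HT7",
    "RN12"
   ],
   "count": 9,
   "kind": "exact"
  },
  {
   "items": [
    "RN4",
    "SP6"
   ],
   "count": 11,
   "kind": "exact"
  },
  {
   "items": [
    "RN12",
    "RN4",
    "SP6"
   ],
   "count": 10,
   "kind": "exact"
  },
  {
   "items": [
    "RN12",
    "RN4"
   ],
   "count": 12,
   "kind": "exact"
  },
  {
   "items": [
    "PC6",
    "RN12"
   ],
   "count": 9,
   "kind": "exact"
  },
  {
   "items": [
    "PC6",
    "ST36"
   ],
   "count": 11,
   "kind": "exact"
  },
  {
   "items": [
    "SP6"
   ],
   "count": 14,
   "kind": "exact"
  },
  {
   "items": [
    "RN12",
    "SP6"
   ],
   "count": 11,
   "kind": "exact"
  },
  {
   "items": [
    "RN12"
   ],
   "count": 22,
   "kind": "exact"
  },
  {
   "items": [
    "RN12",
    "ST36"
   ],
   "count": 13,
   "kind": "exact"
  },
  {
   "items": [
    "ST36"
   ],
   "count": 24,
   "kind": "exact"
  },
  {
   "items": [
    "PC6"
   ],
   "count": 13,
   "kind": "exact"
  },
  {
   "items": [
    "RN4"
   ],
   "count": 13,
   "kind": "exact"
  },
  {
   "items": [
    "SP6",
    "ST36"
   ],
   "count": 8,
   "kind": "at_most"
  },
  {
   "items": [
    "RN4",
    "ST36"
   ],
   "count": 8,
   "kind": "at_most"
  },
  {
   "items": [
    "PC6",
    "SP6"
   ],
   "count": 8,
   "kind": "at_most"
  },
  {
   "items": [
    "PC6",
    "RN4"
   ],
   "count": 8,
   "kind": "at_most"
  },
  {
   "items": [
    "HT7",
    "ST36"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "HT7",
    "SP6"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "HT7",
    "RN4"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "HT7",
    "PC6"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "DU20",
    "HT7"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "DU20",
    "ST36"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "DU20",
    "SP6"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "DU20",
    "RN4"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "DU20",
    "PC6"
   ],
   "count": 6,
   "kind": "at_most"
  },
  {
   "items": [
    "PC6",
    "RN12",
    "ST36"
   ],
   "count": 7,
   "kind": "at_most"
  }
 ],
 "filler_counts": {
  "RN6": 2,
  "LI4": 2,
  "ST19": 2,
  "BL21": 2,
  "BL13": 2,
  "BL20": 2,
  "BL23": 2,
  "RN8": 2,
  "SP9": 2,
  "LI11": 2,
  "SJ6": 2,
  "ST37": 2,
  "ST39": 2,
  "ST25": 2,
  "LR3": 1,
  "GB34": 1,
  "BL17": 1,
  "DU14": 1,
  "SJ5": 1,
  "LI10": 1,
  "SP10": 1,
  "ST21": 1,
  "RN13": 1,
  "RN10": 1,
  "KI3": 1,
  "GB20": 1,
  "DU26": 1,
  "PC5": 1,
  "SP3": 1,
  "ST40": 1,
  "BL18": 1
 }
}
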