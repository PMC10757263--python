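{
 "metabolites": [
  {
   "id": "A"
  },
  {
   "id": "B"
  },
  {
   "id": "C"
  },
  {
   "id": "D"
  },
  {
   "id": "E"
  },
  {
   "id": "F"
  },
  {
   "id": "G"
  },
  {
   "id": "H"
  },
  {
   "id": "I"
  },
  {
   "id": "K"
  },
  {
   "id": "L"
  },
  {
   "id": "T"
  },
  {
   "id": "P"
  }
 ],
 "reactions": [
  {
   "id": "v1",
   "reversible": false,
   "stoichiometry": {
    "A": "1"
   }
  },
  {
   "id": "v2",
   "reversible": false,
   "stoichiometry": {
    "L": "1"
   }
  },
  {
   "id": "v3",
   "reversible": false,
   "stoichiometry": {
    "P": "1"
   }
  },
  {
   "id": "v4",
   "reversible": false,
   "stoichiometry": {
    "A": "-1",
    "B": "2",
    "T": "-2",
    "P": "2"
   }
  },
  {
   "id": "v5",
   "reversible": false,
   "stoichiometry": {
    "B": "-1",
    "C": "1",
    "K": "1",
    "L": "-1"
   }
  },
  {
   "id": "v6",
   "reversible": false,
   "stoichiometry": {
    "C": "-1",
    "D": "1",
    "T": "2",
    "P": "-2"
   }
  },
  {
   "id": "v7",
   "reversible": false,
   "stoichiometry": {
    "D": "-1",
    "F": "1",
    "K": "1",
    "L": "-1"
   }
  },
  {
   "id": "v8",
   "reversible": false,
   "stoichiometry": {
    "D": "-1",
    "E": "1",
    "K": "-1",
    "L": "1"
   }
  },
  {
   "id": "v9",
   "reversible": false,
   "stoichiometry": {
    "F": "-1",
    "H": "1"
   }
  },
  {
   "id": "v10",
   "reversible": false,
   "stoichiometry": {
    "H": "-1",
    "I": "1"
   }
  },
  {
   "id": "v11",
   "reversible": false,
   "stoichiometry": {
    "G": "1",
    "I": "-1",
    "T": "3",
    "P": "-3"
   }
  },
  {
   "id": "v12",
   "reversible": false,
   "stoichiometry": {
    "F": "1",
    "G": "-1",
    "K": "1",
    "L": "-1"
   }
  }
 ]
}
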