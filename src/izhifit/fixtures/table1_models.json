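{
 "units": {
  "t": "ms",
  "V": "mV",
  "I": "pA",
  "C": "pF",
  "G": "nS"
 },
 "models": [
  {
   "name": "CA1 OR-LM",
   "class": "NASP",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 0.527,
      "a": 0.00223,
      "b": 6.15,
      "d": -12,
      "C": 253,
      "Vr": -57.25,
      "Vt": -42.78,
      "Vpeak": 81.81,
      "Vmin": -44.97
     }
    ],
    "links": []
   },
   "working_currents_pA": [
    156,
    108,
    46,
    -195
   ]
  },
  {
   "name": "DG Neurogliaform",
   "class": "D.NASP",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 0.697,
      "a": 0.00107,
      "b": -30.65,
      "d": 111,
      "C": 242,
      "Vr": -74.15,
      "Vt": -9.2,
      "Vpeak": 17.51,
      "Vmin": -39.44
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA3 Giant",
   "class": "ASP.",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 0.609,
      "a": 0.00365,
      "b": 1.84,
      "d": 2,
      "C": 96,
      "Vr": -57.58,
      "Vt": -37.12,
      "Vpeak": 36.42,
      "Vmin": -49.45
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA3 Basket",
   "class": "ASP.SLN",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 0.995,
      "a": 0.00385,
      "b": 9.26,
      "d": -6,
      "C": 45,
      "Vr": -57.28,
      "Vt": -23.16,
      "Vpeak": 18.68,
      "Vmin": -47.33
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA3 Basket-CCK",
   "class": "ASP.NASP",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 0.583,
      "a": 0.00574,
      "b": -1.24,
      "d": 54,
      "C": 135,
      "Vr": -59.0,
      "Vt": -39.4,
      "Vpeak": 18.27,
      "Vmin": -42.77
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA2 Pyramidal",
   "class": "D.ASP.",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 5.943,
      "a": 0.00114,
      "b": -15.89,
      "d": 74,
      "C": 1630,
      "Vr": -72.59,
      "Vt": -58.78,
      "Vpeak": 19.99,
      "Vmin": -62.65
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA1 O-LMR",
   "class": "TSTUT.NASP",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "c1",
    "compartments": [
     {
      "name": "c1",
      "k": 0.326,
      "a": 0.00632,
      "b": 0.4,
      "d": 48,
      "C": 96,
      "Vr": -56.44,
      "Vt": -27.62,
      "Vpeak": 29.48,
      "Vmin": -51.29
     },
     {
      "name": "c2",
      "k": 0.326,
      "a": 0.00632,
      "b": 0.4,
      "d": 48,
      "C": 96,
      "Vr": -56.44,
      "Vt": -27.62,
      "Vpeak": 29.48,
      "Vmin": -51.29
     }
    ],
    "links": [
     {
      "proximal": "c1",
      "distal": "c2",
      "G": 12.0,
      "P": 0.5
     }
    ]
   }
  },
  {
   "name": "CA3c Pyramidal",
   "class": "TSWB.SLN",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "soma",
    "compartments": [
     {
      "name": "soma",
      "k": 3.006,
      "a": 0.00189,
      "b": 19.36,
      "d": 104,
      "C": 244,
      "Vr": -62.29,
      "Vt": -45.27,
      "Vpeak": 17.43,
      "Vmin": -47.37
     }
    ],
    "links": []
   }
  },
  {
   "name": "CA1 Oriens-Bistratified",
   "class": "PSTUT",
   "units": {
    "t": "ms",
    "V": "mV",
    "I": "pA",
    "C": "pF",
    "G": "nS"
   },
   "provenance": "published single-compartment parameter set (hippocampal neuron-type models)",
   "model": {
    "soma": "c1",
    "compartments": [
     {
      "name": "c1",
      "k": 2.91,
      "a": 0.00168,
      "b": 13.67,
      "d": 35,
      "C": 841,
      "Vr": -57.11,
      "Vt": -48.5,
      "Vpeak": 4.12,
      "Vmin": -52.94
     },
     {
      "name": "c2",
      "k": 2.91,
      "a": 0.00168,
      "b": 13.67,
      "d": 35,
      "C": 841,
      "Vr": -57.11,
      "Vt": -48.5,
      "Vpeak": 4.12,
      "Vmin": -52.94
     }
    ],
    "links": [
     {
      "proximal": "c1",
      "distal": "c2",
      "G": 67.0,
      "P": 0.5
     }
    ]
   }
  }
 ]
}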