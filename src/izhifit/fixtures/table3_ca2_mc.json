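{
 "name": "CA2 Pyramidal 4-compartment",
 "class": "D.ASP.",
 "units": {
  "t": "ms",
  "V": "mV",
  "I": "pA",
  "C": "pF",
  "G": "nS"
 },
 "provenance": "published four-compartment parameter set (CA2 pyramidal model)",
 "working_currents_pA": [
  401
 ],
 "model": {
  "soma": "SP",
  "compartments": [
   {
    "name": "SO",
    "k": 0.875,
    "a": 0.004,
    "b": 9.154,
    "d": 41,
    "C": 1163,
    "Vr": -74.633,
    "Vt": -61.327,
    "Vpeak": 7.44,
    "Vmin": -66.761
   },
   {
    "name": "SP",
    "k": 1.029,
    "a": 0.002,
    "b": 11.054,
    "d": 40,
    "C": 1164,
    "Vr": -74.633,
    "Vt": -62.009,
    "Vpeak": 18.314,
    "Vmin": -65.184
   },
   {
    "name": "SR",
    "k": 0.84,
    "a": 0.016,
    "b": 10.912,
    "d": 42,
    "C": 1174,
    "Vr": -74.633,
    "Vt": -62.307,
    "Vpeak": 14.142,
    "Vmin": -63.394
   },
   {
    "name": "SLM",
    "k": 0.833,
    "a": 0.019,
    "b": 9.471,
    "d": 42,
    "C": 1170,
    "Vr": -74.633,
    "Vt": -60.468,
    "Vpeak": 2.444,
    "Vmin": -66.223
   }
  ],
  "links": [
   {
    "proximal": "SP",
    "distal": "SO",
    "G": 170,
    "P": 0.407
   },
   {
    "proximal": "SP",
    "distal": "SR",
    "G": 169,
    "P": 0.169
   },
   {
    "proximal": "SR",
    "distal": "SLM",
    "G": 169,
    "P": 0.348
   }
  ]
 }
}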