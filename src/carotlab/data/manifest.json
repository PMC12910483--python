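[
  {
    "name": "bbd_design.csv",
    "provenance": "measured (published 15-run Box-Behnken fermentation dataset; actual factor levels are a packaged convention)",
    "sha256": "9169f36fe5057a245af775dafee1db23cd68465d08db1b2b0ce77fea90bd77c8"
  },
  {
    "name": "stability_conditions.csv",
    "provenance": "derived from published summary table (single reading per condition; ND = not detected)",
    "sha256": "3cdd414ac80a4568e375ca860f38a1a0b076d3f90a75f2b876b6ee9b75dc0498"
  },
  {
    "name": "factors.json",
    "provenance": "packaged convention reconciling the reported base medium and optimum",
    "sha256": "cd142c3ad0913966219e8d2fe1f08c460c1ee84dbf6b817fded2056e15d3bc21"
  }
]
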