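{
  "description": "Lifestyle category counts reported for a published human-gut virome catalogue of 21499 vOTUs (virulence-score bins at 0.3/0.5/0.7). Note the four counts sum to 21569; the published percentages use the catalogue size 21499 as denominator, and this file preserves both as printed.",
  "catalogue_size": 21499,
  "counts": {
    "temperate": 3419,
    "uncertain_temperate": 11869,
    "uncertain_virulent": 4733,
    "virulent": 1548
  }
}
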