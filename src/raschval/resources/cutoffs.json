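{
  "version": 1,
  "presets": {
    "fhl": {
      "max_score": 6,
      "levels": [["Emerging", 0, 4], ["Expanding", 5, 6]]
    },
    "ihl": {
      "max_score": 10,
      "levels": [["Emerging", 0, 5], ["Expanding", 6, 10]]
    },
    "chl": {
      "max_score": 14,
      "levels": [["Emerging", 0, 8], ["Expanding", 9, 14]]
    },
    "composite": {
      "max_score": 30,
      "levels": [["Emerging", 0, 10], ["Expanding", 11, 19], ["Lower Bridging", 20, 27], ["Upper Bridging", 28, 30]]
    },
    "composite_younger": {
      "max_score": 30,
      "levels": [["Emerging", 0, 10], ["Expanding", 11, 19], ["Lower Bridging", 20, 26], ["Upper Bridging", 27, 30]]
    }
  }
}
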