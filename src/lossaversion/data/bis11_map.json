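{
  "description": "BIS-11 subscale assignment (1-based item numbers) and reverse-scored items. Items are rated 1-5; reversed items score (6 - response).",
  "subscales": {
    "cognitive": [5, 6, 9, 11, 20, 24, 26, 28],
    "motor": [2, 3, 4, 16, 17, 19, 21, 22, 23, 25, 30],
    "nonplanning": [1, 7, 8, 10, 12, 13, 14, 15, 18, 27, 29]
  },
  "reversed": [1, 7, 8, 9, 10, 12, 13, 15, 20, 29, 30]
}
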