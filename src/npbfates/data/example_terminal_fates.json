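{
 "neural": [
  "N@ss4",
  "N@ss8"
 ],
 "neural_crest": [
  "NC@ss4",
  "NC@ss8"
 ],
 "placodal": [
  "PPR@ss4",
  "PPR@ss8"
 ]
}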