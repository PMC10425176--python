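{
 "HH4": [
  "eN",
  "eNPB",
  "NNE"
 ],
 "HH5": [
  "eN",
  "eNPB",
  "NNE"
 ],
 "HH6": [
  "N",
  "NPB",
  "pEpi"
 ],
 "HH7": [
  "N",
  "NC",
  "PPR",
  "pEpi"
 ],
 "ss4": [
  "N",
  "NC",
  "PPR",
  "pEpi"
 ],
 "ss8": [
  "N",
  "NC",
  "PPR",
  "pEpi"
 ]
}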