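{
 "sex": {
  "female": {"positive": 144, "negative": 178},
  "male": {"positive": 53, "negative": 37}
 },
 "age": {
  "lt45": {"positive": 111, "negative": 95},
  "ge45": {"positive": 86, "negative": 120}
 },
 "diameter": {
  "lt0.7": {"positive": 18, "negative": 74},
  "0.7-1.0": {"positive": 37, "negative": 55},
  "1.0-1.5": {"positive": 53, "negative": 62},
  "1.5-2.0": {"positive": 35, "negative": 16},
  "ge2.0": {"positive": 54, "negative": 8}
 },
 "ecs": {
  "presence": {"positive": 61, "negative": 20},
  "absence": {"positive": 136, "negative": 195}
 },
 "multifocality": {
  "presence": {"positive": 13, "negative": 9},
  "absence": {"positive": 184, "negative": 206}
 },
 "location": {
  "upper": {"positive": 26, "negative": 48},
  "middle": {"positive": 106, "negative": 111},
  "lower": {"positive": 57, "negative": 45},
  "isthmus": {"positive": 8, "negative": 11}
 },
 "class_totals": {"positive": 197, "negative": 215}
}
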