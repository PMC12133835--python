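{
  "normal": ["joy", "happy", "elation", "contentment"],
  "depression": ["hurt", "anger", "moody", "bored", "sadness", "broken", "shocking"]
}
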