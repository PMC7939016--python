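{
 "required": {
  "package": "string",
  "version": "string",
  "arm": "string",
  "seed": "number",
  "config": "object",
  "stages": "array"
 },
 "stage": {
  "required": {
   "name": "string",
   "params": "object",
   "warnings": "array",
   "metrics": "object",
   "outputs": "array"
  }
 }
}
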