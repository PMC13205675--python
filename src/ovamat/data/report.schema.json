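{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ovamat run report",
  "type": "object",
  "required": [
    "tool_version",
    "config_hash",
    "seeds",
    "input_checksums",
    "warnings",
    "result"
  ],
  "properties": {
    "tool_version": {"type": "string"},
    "config_hash": {"type": "string", "pattern": "^[0-9a-f]{64}$"},
    "config": {"type": "object"},
    "seeds": {"type": "object"},
    "input_checksums": {
      "type": "object",
      "additionalProperties": {"type": "string", "pattern": "^[0-9a-f]{64}$"}
    },
    "warnings": {"type": "array", "items": {"type": "string"}},
    "result": {}
  }
}
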