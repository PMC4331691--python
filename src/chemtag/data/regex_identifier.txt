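# IDENTIFIER token patterns (full-token match), v1
(?:CHEBI|CHEMBL|CID|CAS|DB|EC|NSC|UNII|ZINC)[:-]\d{1,8}|\d{2,7}-\d{2}-\d
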