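# Post-processing configuration, v1.
# rejection_patterns: full-surface regexes; a mention whose whole surface
#   matches any pattern is discarded.
# action_suffixes: trailing "action words" stripped once from mention ends.
# priorities: tagger families from highest to lowest precedence when
#   equal-length mentions overlap.
rejection_patterns:
  - "(?i)lead"
  - "(?i)gold"
  - "(?i)compounds?"
  - "(?i)chemicals?"
  - "(?i)drugs?"
  - "In"
  - "As"
  - "At"
  - "He"
  - "Be"
  - "No"
action_suffixes:
  - "-based"
  - "-regulated"
  - "-induced"
  - "-treated"
  - "-dependent"
  - "-mediated"
  - "-containing"
  - "-derived"
priorities:
  - crf
  - dict
  - regex
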