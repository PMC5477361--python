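{
  "comment": "ACMG/AMP 2015 combining rules over effective evidence strengths. Each rule lists minimum counts per strength tier; stronger surplus evidence may fill weaker slots.",
  "pathogenic": [
    {"very_strong": 1, "strong": 1},
    {"very_strong": 1, "moderate": 2},
    {"very_strong": 1, "moderate": 1, "supporting": 1},
    {"very_strong": 1, "supporting": 2},
    {"strong": 2},
    {"strong": 1, "moderate": 3},
    {"strong": 1, "moderate": 2, "supporting": 2},
    {"strong": 1, "moderate": 1, "supporting": 4}
  ],
  "likely_pathogenic": [
    {"very_strong": 1, "moderate": 1},
    {"strong": 1, "moderate": 1},
    {"strong": 1, "supporting": 2},
    {"moderate": 3},
    {"moderate": 2, "supporting": 2},
    {"moderate": 1, "supporting": 4}
  ],
  "benign": [
    {"stand_alone": 1},
    {"strong": 2}
  ],
  "likely_benign": [
    {"strong": 1, "supporting": 1},
    {"supporting": 2}
  ]
}
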