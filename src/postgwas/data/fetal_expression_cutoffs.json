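{
  "description": "Published tertile cutoffs for fetal germ cell transcript levels used in replication mode of the gene-scoring rubric: low <= 698, medium 699-2348, high >= 2349.",
  "low_max": 698,
  "medium_max": 2348
}
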