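{
  "COHORT": "cohort",
  "RAW_READS": "sample01.fastq",
  "SAMPLE": "sample01",
  "TARGET_BP": "1000000"
}
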