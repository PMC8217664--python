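{
  "schema_version": "1.0",
  "macro": {
    "COHORT": null,
    "SAMPLE": "sample01",
    "TARGET_BP": "1000000"
  },
  "workflow": [
    {
      "name": "align",
      "command": "echo aligned @{qc.clean_reads} > [bam]",
      "from": [
        {
          "from": "qc",
          "frompid": "clean_reads",
          "topid": "reads"
        }
      ],
      "to": [
        {
          "to": "pindel_somatic",
          "frompid": "bam",
          "topid": "bam"
        },
        {
          "to": "strelka2_somatic",
          "frompid": "bam",
          "topid": "bam"
        },
        {
          "to": "vardict_somatic",
          "frompid": "bam",
          "topid": "bam"
        },
        {
          "to": "varscan2_somatic",
          "frompid": "bam",
          "topid": "bam"
        }
      ]
    },
    {
      "name": "merge",
      "command": "python3 -m flowcall merge --caller strelka2=@{strelka2_somatic.vcf} --caller vardict=@{vardict_somatic.vcf} --caller varscan2=@{varscan2_somatic.vcf} --caller pindel=@{pindel_somatic.vcf} --min-callers 2 --out [merged] --out-table [table]",
      "from": [
        {
          "from": "strelka2_somatic",
          "frompid": "vcf",
          "topid": "vcf_strelka2"
        },
        {
          "from": "vardict_somatic",
          "frompid": "vcf",
          "topid": "vcf_vardict"
        },
        {
          "from": "varscan2_somatic",
          "frompid": "vcf",
          "topid": "vcf_varscan2"
        },
        {
          "from": "pindel_somatic",
          "frompid": "vcf",
          "topid": "vcf_pindel"
        }
      ],
      "to": [
        {
          "to": "report",
          "frompid": "merged",
          "topid": "merged"
        }
      ]
    },
    {
      "name": "pindel_somatic",
      "command": "cat @{align.bam} > /dev/null && cp #COHORT#/pindel.vcf [vcf]",
      "from": [
        {
          "from": "align",
          "frompid": "bam",
          "topid": "bam"
        }
      ],
      "to": [
        {
          "to": "merge",
          "frompid": "vcf",
          "topid": "vcf_pindel"
        }
      ]
    },
    {
      "name": "qc",
      "command": "echo qc of <raw_reads> > [clean_reads]",
      "from": [],
      "to": [
        {
          "to": "align",
          "frompid": "clean_reads",
          "topid": "reads"
        }
      ]
    },
    {
      "name": "report",
      "command": "python3 -m flowcall maf --in @{merge.merged} --sample #SAMPLE# --target-bp #TARGET_BP# --maf [maf] --report-dir . --commands-log \"$(ls ../*.command.log | head -n 1)\"",
      "from": [
        {
          "from": "merge",
          "frompid": "merged",
          "topid": "merged"
        }
      ],
      "to": []
    },
    {
      "name": "strelka2_somatic",
      "command": "cat @{align.bam} > /dev/null && cp #COHORT#/strelka2.vcf [vcf]",
      "from": [
        {
          "from": "align",
          "frompid": "bam",
          "topid": "bam"
        }
      ],
      "to": [
        {
          "to": "merge",
          "frompid": "vcf",
          "topid": "vcf_strelka2"
        }
      ]
    },
    {
      "name": "vardict_somatic",
      "command": "cat @{align.bam} > /dev/null && cp #COHORT#/vardict.vcf [vcf]",
      "from": [
        {
          "from": "align",
          "frompid": "bam",
          "topid": "bam"
        }
      ],
      "to": [
        {
          "to": "merge",
          "frompid": "vcf",
          "topid": "vcf_vardict"
        }
      ]
    },
    {
      "name": "varscan2_somatic",
      "command": "cat @{align.bam} > /dev/null && cp #COHORT#/varscan2.vcf [vcf]",
      "from": [
        {
          "from": "align",
          "frompid": "bam",
          "topid": "bam"
        }
      ],
      "to": [
        {
          "to": "merge",
          "frompid": "vcf",
          "topid": "vcf_varscan2"
        }
      ]
    }
  ]
}
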