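# Siderophore biosynthesis/uptake loci used for locus-completeness calls.
# ent: enterobactin synthesis; ybt: yersiniabactin synthesis and uptake.
loci:
  ent: [entA, entB, entC, entE, entF]
  ybt: [irp1, irp2, fyuA, ybtA, ybtE, ybtS, ybtU, ybtT, ybtD, psn]
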