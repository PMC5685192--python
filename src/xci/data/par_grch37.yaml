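# Pseudoautosomal region boundaries on GRCh37/hg19 (1-based inclusive)
# and the Xp/Xq split at the centromere midpoint.
PAR1:
  chrom: X
  start: 60001
  end: 2699520
PAR2:
  chrom: X
  start: 154931044
  end: 155260560
xp_xq_boundary: 60600000
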