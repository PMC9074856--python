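# Packaged default assay: the six-CpG cardiomyocyte marker island in the
# FAM101A locus, targeted by methylation-independent bisulfite PCR primers.
#
# The insert sequence below is a SYNTHETIC stand-in: the true genomic
# sequence of the 90 bp window chr12:124,207,916-124,208,005 is not
# distributed with this package. The stand-in matches the published assay
# geometry (90 bp insert, six CpGs between the primer footprints, primer
# locus-portions converting cleanly under bisulfite chemistry) so that the
# whole pipeline can be exercised end to end; substitute the real genomic
# sequence via this file format for use on real data.
name: FAM101A_synthetic
locus_label: "chr12:124,207,916-124,208,005"
reference_seq: TATGGCTTGGTAATTCATTTAGAGAACGTTCAGGACGATTTACGTAACGGTTCTACGATTGTCACGTTTTTACTTGTGGGATTTGCATTT
cpg_offsets: [26, 35, 42, 47, 55, 64]
primer_fwd: TATGGTTTGGTAATTTATTTAGAG
primer_rev: AAATACAAATCCCACAAATAAA
adapter_fwd: TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG
adapter_rev: GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG
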