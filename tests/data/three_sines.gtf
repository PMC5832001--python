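chr1	rmsk	exon	5001	5300	.	+	.	gene_id "alu_a"; transcript_id "alu_a"; subfamily "AluYa5";
chr1	rmsk	exon	1001	1300	.	-	.	gene_id "mir_b"; transcript_id "mir_b"; subfamily "MIRb";
chr2	rmsk	exon	2001	2260	.	+	.	gene_id "alu_c"; transcript_id "alu_c"; subfamily "AluSx";
chr1	rmsk	exon	9001	9300	.	.	.	gene_id "strandless"; transcript_id "strandless"; subfamily "AluY";
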