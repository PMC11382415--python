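# Curated reference set: 14 blood-RNA-validated splice-altering VUSs with
# published SpliceAI delta scores (acceptor/donor gain/loss) and which
# splicing tools detected the event (semicolon-separated; "none" = missed
# by all four of rMATS, MAJIQ, FRASER2, LeafCutterMD).
gene	variant	ds_ag	ds_al	ds_dg	ds_dl	observed_class	tools
SF3B4	NM_005850.5:c.417C>T	0.18	0	0.37	0	alt_donor_acceptor	none
MED13L	NM_015335.4:c.2570-4_2574del	0.98	0.99	0	0	alt_acceptor	rMATS;MAJIQ;LeafCutterMD
DKC1	NM_001363.5:c.915+10G>A	0	0	0.87	0.02	alt_donor	rMATS
NF1	NM_000267.3:c.1168_1179del	0	0	0	0.04	exon_skipping	rMATS
NF1	NM_000267.3:c.7832A>G	0.01	0.12	0.43	0	exon_skipping	rMATS
P3H1	NM_022356.4:c.1224-80G>A	0	0	0.62	0	alt_donor	rMATS
TSC2	NM_000548.5:c.4492A>C	0	0	0.23	0.41	alt_donor	rMATS;MAJIQ
UBR4	NM_020765.3:c.8488+3A>G	0.03	0	0.13	0.26	intron_retention	none
SMARCE1	NM_003079.5:c.8-4A>G	0.48	0.22	0	0	alt_acceptor	none
EFTUD2	NM_004247.4:c.702+5G>A	0	0	0.13	0.93	exon_skipping	rMATS
ARID1A	NM_006015.6:c.3198G>A	0	0	0.25	0.03	alt_donor	rMATS
KAT6B	NM_012330.4:c.2629+5G>A	0	0	0.02	0.98	exon_skipping	rMATS
PHF8	NM_015107.3:c.784-2A>G	0.27	0.99	0	0	exon_skipping	rMATS;MAJIQ;LeafCutterMD
WDR26	NM_001379403.1:c.823-10A>G	1.00	0.87	0	0	alt_acceptor	rMATS;MAJIQ;LeafCutterMD
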