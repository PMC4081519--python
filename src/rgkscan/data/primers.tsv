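name	gene	direction	sequence
dr_Gem_for	dr_Gem	forward	GATCACGCGTACCATGACCCTGCTGGCGAGCGTGC
dr_Gem_rev	dr_Gem	reverse	GATCGATCGCGGCCGCTTACAGACTCATCAGGTCATGAC
dr_Rad_for	dr_Rad	forward	GATCACGCGTACCATGACTTTGAACAAAGGAGACAAG
dr_Rad_rev	dr_Rad	reverse	GATCGATCGCGGCCGCTTATAGCACTGAAAGGTCGTGGC
dr_Rem1_for	dr_Rem1	forward	GATCACGCGTACCATGACACTCAACACACAGAAGG
dr_Rem1_rev	dr_Rem1	reverse	GATCGATCGCGGCCGCTCACAGCACAGCGAGGTCATGG
dr_Rem2_for	dr_Rem2	forward	GATCACGCGTACCATGTCGGACCAGGGTTATGGC
dr_Rem2_rev	dr_Rem2	reverse	GATCGATCGCGGCCGCTCACATTAAAGCGCTGAGGTCG
dm_RGK1_for	dm_RGK1	forward	GATCACGCGTACCATGGCGCCCTTCTACAAGCGC
dm_RGK1_rev	dm_RGK1	reverse	GATCGATCGCGGCCGCTTAGAGTACATGCAGATTCTCGC
dm_RGK2_for	dm_RGK2	forward	GATCACGCGTACCATGGCCCAGCAACAGCGCAGC
dm_RGK2_rev	dm_RGK2	reverse	GATCGATCGCGGCCGCTTATAGCACATGCAGATTCTCG
dm_RGK3_for	dm_RGK3	forward	GATCACGCGTACCATGGTGGACGACATCTCACCG
dm_RGK3_rev	dm_RGK3	reverse	GATCGATCGCGGCCGCTTAGAGCACCTGCAGATTCTCGC
dm_RGK2t_for	dm_RGK2t	forward	GATCACGCGTACCATGGCCCAGCAACAGCGCAGC
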