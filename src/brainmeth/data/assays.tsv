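name	forward_primer	reverse_primer	type	origin	chrom	start	end
n1	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TATTATGTTATGGGAGGTTGTTTYGAG	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) ACRTAAAACTTAAAACTCTTACAAATACT	Hypo	panel	chr10	3283768	3284144
n2	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TAAAAGGGAAATTGGATTTTTAGAGAGA	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) ATCCATCCATTTTAATAATAAACACCAC	Hypo	panel	chr9	7209139	7209478
n3	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TGTGTTTGGTTTTTTAATAAAGGAAAGG	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) CTTAAACTTCCCCTTCTCCTTCTC	Hypo	panel	chr16	88677634	88677983
n4	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TTTTTTTTGTTGGTAGTTGGAGGTAG	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) CACAAAATAACAAATAACCTTACTCCCT	Hypo	panel	chr6	112086098	112086366
n5	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) AGGTATGAAAGGTTAGGTTGTTTTTTTA	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) CTCCTTTTCCCATTTTAAACACAATTAT	Hypo	panel	chr6	128387907	128388072
n6	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TAGATGAATTTGTAAAAGGGAAATTGGA	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) CATCCATTTTAATAATAAACACCACACC	Hypo	panel	chr9	7209139	7209478
n7	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TAGGAGGTTTTGGCGTTCGGTTAGTTTT	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) ACCAAAAAAAACTCCTACTACTAAAACA	Hyper	panel	chr14	70039000	70039294
n8	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) AATTGGTAGGTTTGTAGTAGGAGGT	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) TACAAAATAAACTAAAACTATTCCACRC	Hyper	panel	chr17	72353358	72353665
n9	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TTGTTTTTTAGTTTTGTAYGTTTTTTTT	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) TCRTAAATTCAATACCATTAATAACCAA	Hypo	panel	chr1	568193	568528
n10	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) AGGGAAGGGAATTTTAATTGTTTTTTTT	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) ACTTAAAAACATATTTTAAATTTTTATCCCTTACA	Hypo	panel	chr2	201321569	201321769
n11	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) ATTTGATTTTGTGGTAGTGGA	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) AAAATCCCCACCTCTACTTAA	Hypo	external	chr16	72460052	72460163
n12	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TATATGTGTGTAGGTTGAATAAAAT	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) TCCATTTCATATCAATACTAATATT	Hypo	external	chr10	3283855	3283972
n13	(TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG) TTTAGTGTTAGAATTGAAAGAGTAGA	(GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG) TTAACCTTAACTATATCTAACAAAAA	Hypo	panel	chr1	10239929	10240207
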