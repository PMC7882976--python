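biomarker_id	first_detection_day	n_tissue_replicates	rat_asv_id	phylum	family	genus	species	similarity_pct	n_rats	in_both_sample_types	feces_only	multi_kipuka
ASV100	D11	3	e15086c6f06b9ab2db9544a6573e930d	Proteobacteria	Pseudomonadaceae	Pseudomonas	viridiflava	100	1	0	0	0
ASV100	D11	3	93ae0cb4f1180c5bc85da5a5ad99d4a2	Proteobacteria	Pseudomonadaceae	Pseudomonas	viridiflava	99	3	0	0	1
ASV103	D11	2	bd298d360cf7e61a2e1d2abe51467853	Proteobacteria	Enterobacteriaceae	-	-	99	3	0	0	1
ASV103	D11	2	9e7246ddc0eae83c1a74a316fe72f2f1	Proteobacteria	Enterobacteriaceae	-	-	99	2	0	0	1
ASV103	D11	2	910acad922c911e9b2270f96326b9bb1	Proteobacteria	Enterobacteriaceae	-	-	99	1	0	0	0
ASV103	D11	2	12e77d709989ae4da784b662fce24432	Proteobacteria	Enterobacteriaceae	-	-	99	1	0	1	0
ASV135	D4	2	f00f91d78f49cfbe68e6554f920ae5d8	Proteobacteria	Enterobacteriaceae	-	-	99	3	0	0	1
ASV135	D4	2	e15e067244d294ff4e0a4bb7f3149dc9	Proteobacteria	Enterobacteriaceae	-	-	100	1	0	0	0
ASV135	D4	2	813e7aaa81207e1cf91364ee5691a605	Proteobacteria	Enterobacteriaceae	-	-	98	3	0	0	1
ASV142	D4	2	df8da8cdf673547d89adba6a22f7d2ee	Proteobacteria	Enterobacteriaceae	Ewingella	americana	98	3	1	0	1
ASV142	D4	2	239c51edf1db3559615306d8952fe27e	Proteobacteria	Enterobacteriaceae	-	-	98	1	0	0	0
ASV147	D4	2	36d75a97bbb0e49db0d56538ce946b2a	Firmicutes	Carnobacteriaceae	Carnobacterium	NA	97	1	0	0	0
ASV54	D4	3	9cd5c63214c4582ee6d84e0bfd903c71	Proteobacteria	Pseudomonadaceae	Pseudomonas	NA	99	3	1	0	1
ASV54	D4	3	21301da854c631af0c945541ce91efb8	Proteobacteria	Pseudomonadaceae	Pseudomonas	viridiflava	98	1	0	0	0
ASV73	D11	2	868c3e66c9baedb1bf2c6b9328abf35c	Proteobacteria	Enterobacteriaceae	Morganella	morganii	100	2	0	0	1
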