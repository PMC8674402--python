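gene_id	annotation	indels	snps	expr_db
Os03g0213300	Phosphopantetheine attachment site domain containing protein; Hypothetical conserved gene	1	3	High
Os03g0213400	Similar to RNA helicase	0	0	Medium
Os03g0213500	Conserved hypothetical protein	0	0	High
Os03g0213600	Conserved hypothetical protein	3	3	Medium
Os03g0213700	DUF647 domain containing protein	1	0	Medium
Os03g0213800	Mitochondrial substrate carrier family protein	2	0	Medium
Os03g0213900	Conserved hypothetical protein; ROUGH SHEATH2-interacting KH-domain protein	3	3	Medium
Os03g0214000	Diphosphonucleotide phosphatase 1 precursor; nucleotide pyrophosphatase	1	0	High
Os03g0214050	Hypothetical protein	0	0	no data
Os03g0214100	Replication protein A1	1	0	Low
Os03g0214200	Mediator of OsbZIP46 deactivation and degradation, Negative regulation of ABA signaling and drought tolerance; Ninja-family protein 1	0	0	Medium
Os03g0214400	Digalactosyldiacylglycerol synthase 2	4	0	High
Os03g0214600	26S proteasome subunit RPN9a; 26S proteasome non-ATPase regulatory subunit 13	2	0	High
Os03g0214900	Conserved hypothetical protein	4	2	Medium
Os03g0215000	Integral membrane family protein	0	0	High
Os03g0215200	Putative transcription factor, Carpel specification, Midrib formation	0	0	Low
Os03g0215400	MADS-domain-containing protein, sexual reproduction	1	0	Medium
Os03g0215600	Zinc finger, CCHC retroviral-type domain containing protein	0	0	Very low
Os03g0215700	Myosin II heavy chain-like family protein	3	1	Very low
Os03g0215800	Pyridoxal phosphate-dependent enzyme	1	0	Low
Os03g0215900	67kD chloroplastic RNA-binding protein, P67	0	0	Low
Os03g0216000	Zinc-finger protein KNUCKLES	0	0	Very low
Os03g0216300	Pentatricopeptide repeat domain containing protein; Hypothetical conserved gene	1	0	Low
Os03g0216400	Pentatricopeptide repeat domain containing protein	0	0	Low
Os03g0216500	Conserved hypothetical protein	1	0	Low
Os03g0216600	Alpha-glucosidase (EC 3.2.1.20)	0	0	High
Os03g0216700	Citrate transporter, Efficient translocation of Fe	1	0	Medium
Os03g0216733	Hypothetical protein	0	0	no data
Os03g0216766	Hypothetical gene	0	0	no data
Os03g0216800	Polygalacturonase B (Fragment)	1	1	Very low
Os03g0216900	Prefoldin domain containing protein	0	0	Low
Os03g0217000	Inhibin beta B chain precursor	1	0	Low
Os03g0217200	Cyclin-like F-box domain containing protein	0	0	Medium
Os03g0217400	Conserved hypothetical protein	0	0	Low
Os03g0217801	Hypothetical gene	0	0	no data
Os03g0217900	Hypothetical protein	0	0	Medium
Os03g0218100	Sec63 domain containing protein	0	0	no data
Os03g0218200	F-box domain containing protein	1	0	Low
Os03g0218300	Conserved hypothetical protein	3	0	Medium
Os03g0218400	Similar to Hexose transporter	0	0	Low
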