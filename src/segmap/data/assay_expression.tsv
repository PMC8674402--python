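gene_id	expr_assay
Os03g0213300	High
Os03g0214400	High
Os03g0214600	High
Os03g0216600	High
Os03g0214000	Medium
Os03g0215400	Medium
Os03g0215700	Low
Os03g0217000	Low
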