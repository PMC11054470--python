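score	drug	medicine_group	genes
6	Calcitriol	Vitamin D and analogues (A11CC04/D05AX03)	BIRC3;C1S;S100A8;SERPINB3;SNTB1;TNC
6	Estradiol	Hormones (G03CA03)	KRT17;KRT6A;KRT6B;KRT6C;MSMB;PARP9
5	Tretinoin	Retinoids (D10AD01)	BIRC3;FABP7;HAS3;KRT17;KRT6A;LAPTM5;LYZ;S100A8;S100A9;SNTB1;TNC
5	Atorvastatin	Lipid modifying drugs (C10AA05)	DPP4
5	Methotrexate	Immunosuppressants (L04AX03)	AADAC;CD1A;MMP12;S100A9
5	Prednisolone	Glucocorticoids (H02AB06/D07XA)	MMP12
5	Adapalene	Retinoids (D10AD03)	JUN
4	Isotretinoin	Retinoids (D10BA01)	CHI3L2;KRT16;KRT17;KRT6A;MSMB
4	Sulfasalazine	Immunosuppressants (A07EC01)	NFKB1
4	Zinc	Vitamins and minerals (A12CB/D02AB)	S100A8;S100A9;C1R;C1S;KRT16;KRT6A;SERPINA3
4	Acetaminophen	Analgesics (N02BE01)	CD1A;DPP4;IL37;LCE3A;LCP1;MSMB;PARP9;SERPINA3;TYMP
4	Acetylsalicylic acid	Analgesics/antithrombotic drugs (N02BE01/B01AC06)	SERPINA3;TYMP
4	Azathioprine	Immunosuppressants (L04AX01)	DPP4;MMP12
4	Dexamethasone	Glucocorticoids (H02AB02/D07AB)	IL4R;MSMB
4	Fexofenadine	Antihistamines (R06AX26)	CCL22
3	Lidocaine	Analgesics (N01BB02/D04AB01)	EGFR
3	Diazepam	Benzodiazepine derivatives (N05BA01)	TNC
3	Cyclophosphamide	Antineoplastic agents - nitrogen mustard analogues (L01AA01)	BIRC3
3	Cyclosporine	Immunosuppressants - calcineurin inhibitor (L04AD01)	C1R;C1S;DPP4;LAPTM5;LYZ;MT4;PARP9;S100A8;TNC;S100A9;SERPINA3
3	Cytarabine	Antineoplastic agents - pyrimidine analogues (L01BC01)	CDH3;FABP7
3	Diclofenac	NSAID (M01AB05/D11AX18)	MMP12
3	Methylprednisolone	Glucocorticoids (H02AB04/D07AA)	MMP12
3	Rifampicin	Antibiotics (J04AB02)	IL37
3	Selenium	Vitamins and minerals (A12CE)	BIRC3
3	Silver nitrate	Antibacterial (D08AL01)	MT4
3	Simvastatin	Lipid modifying agents (C10AA01)	IL4R
3	Tofacitinib	Immunosuppressants - selective (L04AA29)	KRT16
3	Valproic acid	Anti-epileptics (N03AG01)	C1S;CHP2;DPP4;FABP7;SERPINB3
2	Dupilumab	Interleukin-inhibitor (D11AH05)	IL4R
2	Framycetin	Antibiotics (D09AA)	CXCR4
2	Irbesartan	Angiotensin II receptor blockers (C09CA04)	JUN
2	Niacin	Vitamins and minerals (A11)	NNMT
2	Vildagliptin	Blood glucose lowering drugs - DPP4 inhibitors (A10BH02)	DPP4
2	Alitretinoin	Retinoids (D11AH0)	KRT17;KRT6A;S100A8
2	Bexarotene	Retinoids (L01XF03)	KRT17
2	Indomethacin	NSAID (M01AB01)	BIRC3
2	Nicotine	Drugs used in nicotine dependence (N07BA01)	LTF
2	Progesterone	Hormones (G03DA04)	KRT17;SPRR2B;TNC
2	Rosuvastatin	Lipid modifying agents (C10AA07)	PI3
2	Tamoxifen	Antineoplastic agents - anti-estrogens (L02BA01)	SERPINA3
2	Nadroparin	Antithrombotic drugs (B01AB06)	FOS
1	Erlotinib	Antineoplastic agents - EGFR inhibitors (L01EB02)	EGFR
1	Saxagliptin	Blood glucose lowering drugs - DPP4 inhibitors (A10BH03)	DPP4
1	Etoposide	Antineoplastic agents - podophyllotoxin derivatives (L01CB01)	BIRC3
1	Fluorouracil	Antineoplastic agents - pyrimidine analogues (L01BC02)	SNTB1;TYMP
1	Silicon dioxide	No ATC-code, used as a compound in medicine	AADAC;C1R;C1S;KRT17;LCN2;LOR;PARP9;SERPINA3;SERPINB3;SERPINB4;TMEM173
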