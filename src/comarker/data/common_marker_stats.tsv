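gene	dataset_id	sample_type	fc	p	q
IFI6	DS1	monocyte	8.82	2.05E-03	1.17E-05
IFI6	DS2	pbmc	3.73	5.36E-11	3.67E-05
IFI6	DS3	whole_blood	1.36	5.94E-28	1.34E-05
IFI6	DS4	whole_blood	1.19	7.12E-17	2.86E-06
OAS1	DS1	monocyte	3.38	2.85E-05	1.51E-07
OAS1	DS2	pbmc	2.51	2.80E-08	8.82E-05
OAS1	DS3	whole_blood	1.3	8.94E-30	8.43E-06
OAS1	DS4	whole_blood	1.24	5.33E-21	1.35E-06
OAS2	DS1	monocyte	6.43	3.20E-04	1.81E-06
OAS2	DS2	pbmc	2.08	6.14E-09	7.11E-05
OAS2	DS3	whole_blood	1.22	3.04E-29	1.02E-05
OAS2	DS4	whole_blood	1.21	1.19E-15	3.16E-06
EIF2AK2	DS1	monocyte	3.08	4.96E-04	3.61E-06
EIF2AK2	DS2	pbmc	2.04	1.70E-10	4.34E-05
EIF2AK2	DS3	whole_blood	1.12	2.67E-29	9.94E-06
EIF2AK2	DS4	whole_blood	1.22	1.78E-11	5.27E-06
PLSCR1	DS1	monocyte	2.36	5.45E-05	1.05E-06
PLSCR1	DS2	pbmc	2.02	3.36E-12	2.35E-05
PLSCR1	DS3	whole_blood	1.22	9.46E-35	3.01E-06
PLSCR1	DS4	whole_blood	1.19	2.58E-13	4.37E-06
IFI27	DS1	monocyte	251.66	6.78E-02	1.78E-04
IFI27	DS2	pbmc	74.06	1.14E-07	1.04E-04
IFI27	DS3	whole_blood	1.4	6.06E-16	1.25E-04
IFI27	DS4	whole_blood	1.87	3.55E-18	2.41E-06
IFI44L	DS1	monocyte	11.7	1.07E-03	6.62E-06
IFI44L	DS2	pbmc	5.55	4.72E-10	5.04E-05
IFI44L	DS3	whole_blood	1.35	5.55E-22	4.43E-05
IFI44L	DS4	whole_blood	1.52	1.24E-24	4.52E-07
STAT1	DS1	monocyte	2.68	4.38E-03	2.32E-05
STAT1	DS2	pbmc	1.63	5.11E-09	6.82E-05
STAT1	DS3	whole_blood	1.07	8.85E-17	1.10E-04
STAT1	DS4	whole_blood	1.1	6.93E-15	3.31E-06
RNASE2	DS1	monocyte	3.8	1.87E-02	7.21E-05
RNASE2	DS2	pbmc	3	1.53E-11	2.98E-05
RNASE2	DS3	whole_blood	1.06	2.67E-06	4.35E-04
RNASE2	DS4	whole_blood	1.17	4.63E-10	7.83E-06
GSTO1	DS1	monocyte	1.02	0.889	9.31E-04
GSTO1	DS2	pbmc	1.65	3.10E-15	5.87E-06
GSTO1	DS3	whole_blood	1.01	5.76E-04	5.81E-04
GSTO1	DS4	whole_blood	1.04	6.52E-06	3.01E-05
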