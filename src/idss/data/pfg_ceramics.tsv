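Assemblage	Parkin Punctate	Barton/Kent/MPI	Painted	Fortune Noded	Ranch Incised	Walls Engraved	Wallace Incised	Rhodes Incised	Vernon Paul Applique	Hull Engraved
10-P-1	39	62	46	0	0	0	0	0	0	6
11-N-9	528	198	13	0	19	0	0	0	0	0
11-N-1	865	323	59	17	35	0	0	0	4	0
11-O-10	404	208	6	16	4	0	0	0	0	0
11-N-4	764	470	18	5	9	0	0	0	0	0
13-N-5	35	11	33	0	0	0	0	0	0	0
13-N-4	71	67	96	0	3	4	0	0	0	0
13-N-16	42	56	69	0	1	3	0	0	0	0
13-O-11	35	65	24	0	0	2	0	1	0	1
13-O-10	61	74	79	0	2	8	0	2	0	0
13-P-1	244	40	18	1	16	21	0	14	0	6
13-P-8	83	25	43	0	18	17	0	3	0	3
13-P-10	30	15	12	0	12	12	0	7	2	1
13-O-7	590	498	67	10	21	19	12	8	7	1
13-O-5	923	637	42	12	33	27	15	13	5	2
13-N-21	426	69	105	4	4	0	1	4	1	0
12-O-5	204	156	42	7	8	4	2	1	0	0
Holden Lake	27	294	7	24	2	0	2	1	3	0
13-N-15	728	364	160	9	5	8	14	3	7	2
12-N-3	549	328	77	19	4	0	3	1	2	0
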