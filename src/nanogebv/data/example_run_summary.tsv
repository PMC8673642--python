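sample_id	mean_read_length	yield_gb	mean_base_quality	effective_read_pct
DM1	879	25.87	20.5	83.2
DM2	1698	21.95	20.2	84.9
DM3	1710	19.74	20.7	86.3
DM4	2004	15.98	20.8	87.3
DM5	1990	21.15	20.9	87.9
DM6	1007	26.00	20.2	81.3
DM7	1678	20.7	20.5	89.1
DM8	2570	13.57	21.1	89.2
DM9	2456	19.22	20.1	87.4
DM10	2504	16.93	20.5	87.6
DM11	1637	23.69	21.2	85.2
DM12	1941	14.90	18.2	81.2
DM13	1999	18.59	20.9	86.6
DM14	1729	34.96	20.9	87.1
DM15	1847	24.83	20.7	86.9
DM16	2597	17.35	20.7	88.0
DM17	1374	21.54	20.3	85.6
DM18	1132	30.75	20.2	85.6
DM19	1351	41.13	21.6	92.1
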