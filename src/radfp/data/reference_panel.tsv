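marker	chromosome	position	variation_type	pic	maf	gene_diversity	heterozygosity	missing_rate
Chr1-21	1	18753042	T/C	0.321	0.279	0.402	0.255	0.053
Chr1-45	1	58808047	T/A	0.327	0.290	0.412	0.225	0.065
Chr2-16	2	14156674	C/T	0.290	0.229	0.353	0.240	0.017
Chr2-26	2	44476246	G/A	0.292	0.231	0.356	0.234	0.017
Chr2-27	2	45748274	A/G	0.360	0.379	0.471	0.294	0.045
Chr2-33	2	54832993	G/T	0.368	0.414	0.485	0.260	0.081
Chr3-01	3	301586	A/G	0.354	0.358	0.459	0.365	0.053
Chr3-02	3	362352	G/A	0.324	0.283	0.406	0.123	0.087
Chr3-17	3	29949211	G/A	0.266	0.197	0.317	0.315	0.003
Chr4-03	4	1251819	T/A	0.374	0.471	0.498	0.257	0.039
Chr4-07	4	2932692	C/G	0.316	0.268	0.393	0.185	0.011
Chr4-23	4	34449708	C/T	0.304	0.249	0.374	0.280	0.017
Chr4-33	4	44369429	T/G	0.367	0.413	0.485	0.368	0.045
Chr5-12	5	11242018	A/G	0.359	0.376	0.469	0.334	0.034
Chr5-22	5	33498683	T/C	0.266	0.197	0.316	0.188	0.045
Chr5-24	5	35234907	T/C	0.315	0.268	0.392	0.277	0.067
Chr5-34	5	43324346	C/T	0.364	0.394	0.478	0.288	0.045
Chr5-36	5	44922478	G/A	0.195	0.125	0.219	0.148	0.011
Chr6-06	6	30694641	G/A	0.318	0.272	0.396	0.216	0.025
Chr6-15	6	38117650	A/G	0.355	0.362	0.462	0.313	0.003
Chr6-19	6	42865438	A/T	0.375	0.482	0.499	0.269	0.039
Chr6-20	6	43227414	T/A	0.350	0.346	0.453	0.297	0.006
Chr7-02	7	16504349	C/T	0.232	0.159	0.268	0.149	0.003
Chr7-12	7	27487519	G/C	0.316	0.269	0.393	0.305	0.014
Chr7-23	7	36882600	G/A	0.306	0.252	0.377	0.147	0.025
Chr8-10	8	20479094	G/A	0.360	0.379	0.471	0.249	0.028
Chr8-23	8	35858487	G/T	0.370	0.432	0.491	0.305	0.034
Chr9-01	9	652195	G/A	0.276	0.209	0.331	0.332	0.020
Chr9-02	9	1929299	A/G	0.321	0.278	0.401	0.211	0.039
Chr9-14	9	15485852	G/T	0.246	0.174	0.287	0.151	0.031
Chr9-22	9	40713031	C/T	0.361	0.383	0.472	0.273	0.042
Chr9-24	9	42576246	C/T	0.327	0.289	0.411	0.237	0.028
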