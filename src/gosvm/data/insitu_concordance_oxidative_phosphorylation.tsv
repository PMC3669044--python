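gene_id	sample_id	fish_match	gene_precision	prob_score
CG12934	LP05346		1	0.814
CG1715	LD33960	+	1	0.81
CG33316	SD08735		0.975	0.656
CG5523	GH14535		0.975	0.754
CG10675	GH14673		0.975	0.79
CG9921	GH07174		0.975	0.714
CG8486	GH04578		0.975	0.594
CG8086	GH25625		0.975	0.752
CG10075	GH25609	+	0.975	0.679
CG30116	GH04922		0.975	0.677
CG5532	GH01442	+	0.975	0.662
CG12239	GH14380		0.975	0.66
CG8740	GH05582	+	0.975	0.658
CG18616	GH04932	+	0.975	0.737
CG3420	GH11502	+	0.975	0.682
CG15669	GH02495		0.975	0.629
CG11203	GH26638		0.975	0.691
CG6044	GH12587		0.975	0.61
CG5903	GH13386	-	0.975	0.768
CG14823	GH02020		0.975	0.656
CG13367	GH14959		0.975	0.7
CG6424	GH08256		0.975	0.743
CG7083	GH27162		0.947	0.68
CG3631	LD29155	+	0.925	0.655
CG4281	GH10944	+	0.925	0.604
CG12706	GH14695		0.925	0.648
CG10249	GH11802		0.925	0.56
CG14292	GH14813		0.912	0.592
CG4972	GH14975		0.912	0.592
CG32795	HL08104	-	0.912	0.532
CG4975	GH18454		0.912	0.638
CG6550	GH28477	+	0.912	0.609
CG3971	GH11554	+	0.912	0.549
CG6659	LD45943	+	0.912	0.578
CG15386	GH19557		0.906	0.516
CG1231	GH01151		0.906	0.582
CG15067	GH14961		0.906	0.545
CG6008	GH05862		0.898	0.557
CG5608	LD32461		0.898	0.537
CG8401	GH01937		0.897	0.548
CG6094	GH26345		0.897	0.553
CG9813	GH04365		0.892	0.522
CG13220	GH06079	+	0.885	0.538
CG9056	GH11503		0.885	0.559
CG4577	GH23863		0.875	0.535
CG5325	GM14611		0.871	0.539
CG7710	LP03578		0.871	0.544
CG14125	GH07601		0.868	0.502
CG1859	GH26443		0.868	0.52
CG5325	GH03076		0.829	0.505
CG1135	GH01794		0.829	0.489
CG4757	SD01814		0.826	0.496
CG5989	GH26459	+	0.826	0.481
CG3153	GH04701		0.812	0.468
CG1927	GH11112		0.812	0.462
CG7217	LD45324		0.812	0.457
CG6123	GH13094		0.812	0.47
CG2269	GH06015	-	0.809	0.48
CG4589	LP05955		0.807	0.489
CG14438	GH25521		0.8	0.47
CG8206	GH04557		0.794	0.437
CG9336	GH22472		0.794	0.453
CG7570	GH27163		0.794	0.459
CG10973	LD28549		0.792	0.452
CG7506	GH02466		0.788	0.467
CG6455	GH04666		0.786	0.463
CG17828	GH04984	+	0.778	0.432
CG15765	GH28601		0.778	0.447
CG10585	GH23839	+	0.775	0.432
CG10039	GH11404		0.775	0.436
CG14817	GH01621		0.771	0.433
CG17666	GH08313		0.762	0.42
CG11737	GH22337	+	0.761	0.439
CG7358	GH14795		0.759	0.436
CG5773	GH07612		0.758	0.432
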