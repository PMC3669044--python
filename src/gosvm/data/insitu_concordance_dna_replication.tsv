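gene_id	sample_id	fish_match	gene_precision	prob_score
CG5924	LD38710		0.923	0.705
CG1109	LD27350		0.923	0.736
CG7663	LD46979	+	0.923	0.724
CG7384	LD46023		0.923	0.76
CG14464	LD29015		0.923	0.707
CG16892	LD26813	+	0.923	0.728
CG1578	LD28359	+	0.923	0.755
CG16892	LD42637		0.923	0.739
CG11122	LD29040		0.86	0.644
CG9300	LD21924		0.86	0.666
CG3287	SD03445		0.86	0.643
CG1960	GH21591		0.86	0.66
CG1024	LD28076		0.86	0.652
CG13096	SD03546		0.86	0.664
CG11596	LD45925		0.86	0.682
CG4857	LD29423	+	0.86	0.638
CG4949	LD46305	+	0.86	0.669
CG11943	SD04935		0.86	0.703
CG2469	LD30285	+	0.86	0.677
CG11596	LD42227	+	0.839	0.66
CG12785	LD27528		0.839	0.616
CG11329	LD26217		0.839	0.619
CG6066	LD27582		0.839	0.621
CG17050	LD35611		0.839	0.647
CG18004	LD27741		0.839	0.662
CG1647	LD30287		0.839	0.591
CG31697	SD02518		0.839	0.618
CG15736	LD33780	+	0.83	0.619
CG2691	LD46946		0.829	0.61
CG7728	LD39680	+	0.812	0.592
CG31163	SD09611	+	0.812	0.598
CG3680	LD27862		0.81	0.63
CG3362	LD28544		0.81	0.595
NA	LD42550		0.81	0.612
CG11906	LD27134		0.798	0.566
CG1109	LD26389		0.798	0.592
CG8290	LD37351	+	0.798	0.575
CG2910	GH11110		0.798	0.598
CG10364	LD32040	-	0.798	0.58
CG5877	LD29352		0.79	0.572
CG10625	LD39545	-	0.79	0.568
CG17509	GH12788		0.787	0.568
CG11409	LD40802		0.787	0.607
CG30007	LD29335		0.787	0.58
CG17681	LD30009		0.787	0.573
CG18622	LD26416		0.787	0.539
CG31152	LD29477	+	0.787	0.545
CG11990	LD47989	+	0.787	0.549
CG6724	LD40657		0.783	0.589
CG32069	LD47413		0.783	0.565
CG2962	LD27487		0.783	0.578
CG6049	LD27763		0.776	0.558
CG2260	LD30339		0.772	0.563
CG3735	LD35854		0.771	0.553
CG7110	LD39933	-	0.771	0.577
CG12202	LD30511	+	0.771	0.584
CG9591	LD26057	+	0.771	0.554
CG12340	LD26050		0.771	0.552
CG30020	LD40262		0.771	0.549
CG12050	LD30416	+	0.771	0.561
CG6151	LD28933		0.766	0.567
CG14657	LD28447		0.766	0.556
CG4203	LD29184		0.761	0.537
CG4281	SD03946		0.76	0.548
CG14005	LD30293		0.76	0.566
CG9028	LD27194	+	0.76	0.555
CG7824	LD26655		0.76	0.542
CG7407	LD29166	-	0.758	0.548
CG3338	LD27356	+	0.756	0.524
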