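bin_center	free_energy	probability	error
0.1	1.737906456	0.01705099704	0.475920999
0.3	0.3419789787	0.06886417986	0.4863927587
0.5	0	0.09694222046	0.4784068637
0.7	0.8034908002	0.04340715701	0.5345176986
0.9	1.222907381	0.02853717876	0.4629559797
1.1	2.279105175	0.009924534866	0.5329890448
1.3	3.011950095	0.004769135446	0.533679496
1.5	5.244428912	0.0005115480411	0.5024960815
1.7	2.760144736	0.006134756578	0.7423485481
1.9	2.34509776	0.009290732292	0.5141514401
2.1	1.349792657	0.02513653785	0.5010261103
2.3	2.201915738	0.01072094599	0.6409601894
2.5	0.6786144846	0.04918066956	0.7342610167
2.7	1.123313454	0.03152565573	0.6645648839
2.9	1.388810715	0.02417464655	0.6505439947
3.1	1.019011147	0.03499145851	0.6206175717
3.3	0.9264669236	0.03838428811	0.4099442766
3.5	2.241455553	0.01030531295	0.5408838902
3.7	1.350311108	0.02512350917	0.7022620057
3.9	1.759658217	0.0166841125	0.5896612951
4.1	0.9912778688	0.03597546819	0.5935955247
4.3	0.7438567852	0.04607444005	0.5850500706
4.5	0.6678533457	0.04971276743	0.4506450518
4.7	0.4256683787	0.06333554836	0.5218171798
4.9	0.0957900254	0.08808701302	0.4721131522
5.1	0.5708579082	0.05477627857	0.4487171046
5.3	0.8350717708	0.04205773701	0.5572928595
5.5	0.9324629174	0.03815482477	0.445493909
5.7	1.849265687	0.01525411723	0.4580993608
5.9	1.871933582	0.01491222809	1.035037033
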