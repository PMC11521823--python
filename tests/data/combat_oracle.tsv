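21.4856279537	21.1434541079	21.1264799619	20.9010175669	20.5181029960	19.7168184253	21.8507668539	20.6743209947	21.1346253336	21.3489049250
17.0166627834	16.4483628746	16.1365029081	18.1449788627	17.1361180970	16.3678254073	17.4397568078	16.5749808630	17.0426277090	17.2286229326
18.9892997195	19.0012206943	19.5377651154	19.5645675257	19.8280832338	18.7007000777	18.7807358141	19.5234119546	19.7441790061	19.9251896225
19.9636322870	20.2570314692	19.5881248709	19.3750520188	19.3996478828	19.8330526459	19.6718544430	20.1130299680	20.2813079453	20.7047580293
23.6909907821	22.9724748534	23.9500931535	22.4353549052	23.1438826629	23.2448511599	21.9345255153	23.2092493392	23.7164314349	24.0312804011
18.9345677474	19.3815968756	19.6458273264	20.2278253431	18.4582599322	19.6746274632	18.5160232818	18.8428606285	19.3422356779	19.7020580104
18.8286825877	17.2247530988	17.9925147484	16.9169252337	17.0920321123	17.6362555654	16.6257505823	17.8778261766	16.6052093171	17.8466710823
21.5087233128	21.8972348532	22.4145327328	20.6793342402	21.9933223275	21.6369237554	21.9789986455	21.2146352798	22.2289728243	21.1830671928
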