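20.5510783667	20.2338106718	20.2180720400	20.0090206025	19.6539776185	20.3612277280	22.9374430081	21.5171754149	22.0728791309	22.3315687740
16.1327702764	15.4748215926	15.1137660103	17.4390771540	16.2710695532	17.2560631618	18.3333369784	17.4642510629	17.9342286215	18.1211508297
18.3347881287	18.3464049745	18.8692610258	18.8953796506	19.1521725220	19.2553361886	19.3491088732	20.2192543692	20.4779128141	20.6899912208
19.2685099483	19.5908101831	18.8560134734	18.6219520499	18.6489707098	20.5098717740	20.3229952725	20.8344484847	21.0295325435	21.5204367152
22.6956591697	21.9803884989	22.9535912762	21.4456945132	22.1510221257	24.2406465306	22.7280889358	24.1995500257	24.7850091702	25.1484510344
18.0847453699	18.5832790210	18.8779528198	19.5270058186	17.5535596838	20.5034190236	19.2851973241	19.6288525209	20.1539235772	20.5322610461
18.0526797158	16.2703572163	17.1235112183	15.9282919736	16.1228746730	18.5706395433	17.4921208903	18.8284694546	17.4701970621	18.7952174164
20.7035426604	21.1427440533	21.7275347883	19.7659415906	21.2513682463	22.4175104205	22.7710760935	21.9810366734	23.0294472610	21.9484081694
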