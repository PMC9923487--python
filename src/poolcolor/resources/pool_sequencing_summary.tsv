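color	site	raw_sequences	after_trimming	pct_deleted	properly_paired	pct_properly_paired	properly_paired_after_filters	pct_properly_paired_after_filters
red	Takapoto	933451922	804525582	16.02	652910874	81.15	491651124	75.30
red	Katiu	919931270	825237588	11.47	675882634	81.90	506143676	74.89
red	Gambier	977173146	900905220	8.46	746316126	82.84	545397822	73.08
red	Hatchery	875890480	757998130	15.55	631284132	83.28	472079359	74.78
yellow	Takapoto	938782098	821910616	14.22	671154850	81.66	507808553	75.66
yellow	Katiu	943199888	866874884	8.80	709770466	81.88	522722833	73.65
yellow	Gambier	978499586	884295558	10.65	729092800	82.45	540454292	74.13
yellow	Hatchery	898214928	790138682	13.68	653342130	82.69	490391020	75.06
green	Takapoto	911432464	785142178	16.08	632289464	80.53	472054295	74.66
green	Katiu	898068018	785537094	14.32	649464162	82.68	475609233	73.23
green	Gambier	949968516	867379084	9.52	713228138	82.23	530586280	74.39
green	Hatchery	901035306	789581510	14.11	654043378	82.83	490202797	74.95
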