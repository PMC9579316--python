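# Published forensic-parameter battery for a 48-locus MH identification
# panel (Ae >= 3.0) typed in 92 China Eastern Han individuals.
no	locus	ae	he	pd	ped	pet	tpi
1	MH01CP008	3.2825	0.6957	0.8511	0.2746	0.4749	1.6429
2	MH01CP012	3.0628	0.6413	0.8282	0.2520	0.4435	1.3939
3	MH01CP016	3.0778	0.7174	0.8072	0.2430	0.4336	1.7692
4	MH01KK117	4.2575	0.7174	0.9126	0.3237	0.5304	1.7692
5	MH01KK205	4.1684	0.6739	0.9064	0.3595	0.5624	1.5333
6	MH01KK211	3.0067	0.6087	0.8339	0.2465	0.4414	1.2778
7	MH02KK134	3.4696	0.6739	0.8826	0.3137	0.5162	1.5333
8	MH02KK136	3.6357	0.6739	0.8726	0.3135	0.5126	1.5333
9	MH04CP002	3.6601	0.7253	0.8702	0.3029	0.5048	1.8200
10	MH04CP003	3.5069	0.7065	0.8705	0.2916	0.4930	1.7037
11	MH04CP007	3.2992	0.7500	0.8360	0.2731	0.4705	2.0000
12	MH04KK030	3.9991	0.7500	0.8757	0.3432	0.5452	2.0000
13	MH05CP004	3.8808	0.7717	0.8863	0.3314	0.5339	2.1905
14	MH05CP006	3.1653	0.6413	0.8433	0.2586	0.4535	1.3939
15	MH05KK020	3.2623	0.7065	0.8353	0.2680	0.4624	1.7037
16	MH05KK170	6.0544	0.8696	0.9402	0.4999	0.6851	3.8333
17	MH06CP003	3.5333	0.6739	0.8748	0.2919	0.4918	1.5333
18	MH06CP007	3.4660	0.7500	0.8507	0.2908	0.4926	2.0000
19	MH09KK153	4.4786	0.7363	0.9071	0.3924	0.5919	1.8958
20	MH10CP003	3.2953	0.7500	0.8440	0.2698	0.4663	2.0000
21	MH10KK163	4.2341	0.7391	0.9050	0.3760	0.5757	1.9167
22	MH11CP003	3.5766	0.7283	0.8556	0.2959	0.4968	1.8400
23	MH11CP005	3.4205	0.6739	0.8585	0.2821	0.4801	1.5333
24	MH11KK180	3.6186	0.7500	0.8828	0.3253	0.5251	2.0000
25	MH12KK046	3.9226	0.7609	0.8781	0.3184	0.5231	2.0909
26	MH12KK202	3.5811	0.7826	0.8549	0.2979	0.5001	2.3000
27	MH13CP008	3.0987	0.6630	0.8384	0.2476	0.4398	1.4839
28	MH13KK213	3.8781	0.7935	0.8698	0.3262	0.5290	2.4211
29	MH13KK217	4.5628	0.7609	0.9168	0.4011	0.6015	2.0909
30	MH13KK218	7.0814	0.7935	0.9565	0.5481	0.7237	2.4211
31	MH13KK225	3.1897	0.7283	0.8336	0.2634	0.4599	1.8400
32	MH14CP003	3.1021	0.6522	0.8476	0.2643	0.4554	1.4375
33	MH14CP004	3.7493	0.7935	0.8741	0.3140	0.5168	2.4211
34	MH15CP001	3.5257	0.6515	0.8701	0.2915	0.4915	1.4348
35	MH15KK066	3.2940	0.6630	0.8606	0.2748	0.4748	1.4839
36	MH16KK255	4.3350	0.7935	0.9057	0.3819	0.5818	2.4211
37	MH16KK302	3.8238	0.7717	0.8778	0.3239	0.5256	2.1905
38	MH17CP001	3.2883	0.6957	0.8490	0.2717	0.4684	1.6429
39	MH17CP006	3.1227	0.6630	0.8367	0.2539	0.4481	1.4839
40	MH17KK272	3.2615	0.7473	0.8468	0.2802	0.4793	1.9783
41	MH18CP003	3.4939	0.7283	0.8615	0.2864	0.4858	1.8400
42	MH18CP005	3.6953	0.7174	0.8719	0.3036	0.5055	1.7692
43	MH19CP007	3.5690	0.6848	0.8693	0.2939	0.4941	1.5862
44	MH19KK299	3.4582	0.7717	0.8594	0.3067	0.5066	2.1905
45	MH20KK058	3.6287	0.7065	0.8648	0.2982	0.4994	1.7037
46	MH20KK307	3.7352	0.7174	0.8830	0.3217	0.5232	1.7692
47	MH21KK315	4.5804	0.7439	0.9164	0.4033	0.6024	1.9524
48	MH21KK324	3.5208	0.7826	0.8478	0.3042	0.5019	2.3000
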