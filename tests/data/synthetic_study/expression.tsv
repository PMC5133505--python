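probe_id	S0000	S0001	S0002	S0003	S0004	S0005	S0006	S0007	S0008	S0009	S0010	S0011	S0012	S0013	S0014	S0015	S0016	S0017	S0018	S0019	S0020	S0021	S0022	S0023	S0024	S0025	S0026	S0027	S0028	S0029
PROBE0000	0.232774	1.44493	0.291433	0.00363445	-0.550877	0.748085	-1.24584	0.159926	-0.526732	0.429796	1.12968	1.95413	1.05599	0.500136	-0.00700709	-1.00928	-0.264515	1.31671	0.968371	-1.4771	-1.10054	0.0371343	0.0561687	-0.144145	1.34524	-0.955419	0.512502	-0.708307	-1.00877	0.372021
PROBE0001	-0.139093	-0.776301	0.286808	0.9114	1.29958	1.22484	0.851599	0.0100384	-0.282617	-0.459708	-1.49323	1.82611	-2.4417	-0.0546696	-1.73757	0.209038	-0.758495	1.67953	0.333357	0.155344	1.32731	0.143079	0.615833	-0.226704	-0.541355	-1.63261	-1.27236	-0.866386	-0.313307	0.373842
PROBE0002	-1.6243	-2.45015	-0.739998	-0.860998	0.179933	-0.333467	0.142707	1.7487	0.121298	-0.745858	-0.892861	0.141778	1.59652	-0.173015	-0.531391	0.0689825	-0.342801	0.713301	-0.398047	0.482266	0.69538	1.13688	-0.973719	-1.06524	1.69957	0.0327486	-1.62336	-0.0400793	0.376688	-0.0979301
PROBE0003	1.33656	0.359738	-0.518003	0.692407	-0.791822	3.15645	0.12512	0.0789806	-2.72106	-0.651398	1.32438	-0.235674	-0.293232	-0.840516	-1.39121	2.19551	1.62183	0.0933195	-0.466763	0.431167	-1.87159	0.749742	0.944264	-0.892587	3.30624	-1.17738	-0.0149036	-0.163369	-0.592491	-0.595405
PROBE0004	0.428002	1.07489	0.334918	-1.46717	0.501559	-1.98159	0.0315291	-0.51694	0.0435318	-1.32134	-0.0780721	0.0535024	0.97887	0.452739	1.47085	-0.940781	-1.63954	-0.73035	-1.03951	0.356398	0.23792	1.63386	1.47022	0.682158	-1.24518	0.0596306	-1.39997	-0.502363	-0.685324	0.455762
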