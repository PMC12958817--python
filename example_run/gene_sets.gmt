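set0000	na	gene00004	gene00157	gene00005	gene00086	gene00065	gene00132	gene00024	gene00091	gene00042	gene00028	gene00108	gene00191	gene00038	gene00034
set0001	na	gene00177	gene00114	gene00039	gene00138	gene00043	gene00053	gene00069	gene00136	gene00027	gene00028	gene00129	gene00101
set0002	na	gene00067	gene00046	gene00091	gene00113	gene00093	gene00005	gene00135	gene00129	gene00018	gene00121
set0003	na	gene00168	gene00105	gene00072	gene00069	gene00077	gene00038	gene00032	gene00036	gene00177	gene00163	gene00156	gene00146	gene00114	gene00106	gene00097	gene00195	gene00118	gene00191
set0004	na	gene00177	gene00189	gene00164	gene00025	gene00154	gene00123	gene00080	gene00008	gene00128	gene00028	gene00174	gene00148	gene00055	gene00139	gene00131	gene00098	gene00022	gene00063	gene00018	gene00106	gene00003	gene00136	gene00103	gene00199	gene00035	gene00129	gene00013	gene00176
set0005	na	gene00188	gene00029	gene00002	gene00096	gene00152	gene00069	gene00195	gene00113	gene00004	gene00003	gene00058	gene00044	gene00067	gene00082	gene00179	gene00070	gene00117	gene00022	gene00071	gene00023
set0006	na	gene00115	gene00092	gene00147	gene00107	gene00078	gene00177	gene00173	gene00106	gene00033	gene00117	gene00025	gene00071	gene00180	gene00087	gene00075	gene00141	gene00124	gene00088	gene00192	gene00067
set0007	na	gene00110	gene00072	gene00000	gene00162	gene00169	gene00034	gene00078	gene00017	gene00049	gene00001	gene00070	gene00045	gene00141	gene00094	gene00144	gene00148	gene00161	gene00065	gene00197	gene00097	gene00107	gene00159	gene00127	gene00173
set0008	na	gene00099	gene00041	gene00194	gene00112	gene00018	gene00115	gene00013	gene00087	gene00119	gene00098	gene00163	gene00155	gene00079	gene00040
set0009	na	gene00077	gene00165	gene00182	gene00017	gene00039	gene00095	gene00030	gene00023	gene00181
set0010	na	gene00150	gene00106	gene00164	gene00156	gene00179	gene00110	gene00193	gene00071	gene00182	gene00043	gene00057	gene00075	gene00006
set0011	na	gene00161	gene00151	gene00145	gene00049	gene00143	gene00062	gene00041	gene00075	gene00110	gene00179	gene00195	gene00118	gene00066
set0012	na	gene00077	gene00141	gene00092	gene00113	gene00095	gene00133	gene00052	gene00193	gene00128	gene00180	gene00063	gene00137	gene00081	gene00010	gene00159	gene00061	gene00094	gene00196	gene00038	gene00078	gene00136	gene00178	gene00114	gene00195	gene00042	gene00118	gene00182	gene00048
set0013	na	gene00198	gene00075	gene00143	gene00080	gene00074	gene00116	gene00055	gene00159	gene00083	gene00128	gene00021	gene00097	gene00088	gene00029	gene00093	gene00118	gene00112
set0014	na	gene00183	gene00180	gene00105	gene00152	gene00029	gene00067	gene00110
set0015	na	gene00106	gene00011	gene00064	gene00022	gene00133	gene00018	gene00080	gene00198	gene00178	gene00142
set0016	na	gene00117	gene00121	gene00016	gene00046	gene00101	gene00132	gene00007	gene00022	gene00165	gene00081	gene00160	gene00143	gene00127	gene00038	gene00106	gene00091	gene00137	gene00139	gene00032	gene00128	gene00003	gene00135	gene00152	gene00099
set0017	na	gene00073	gene00164	gene00179	gene00021	gene00109	gene00181	gene00154
set0018	na	gene00116	gene00178	gene00165	gene00007	gene00037	gene00131	gene00170	gene00111	gene00075
set0019	na	gene00121	gene00172	gene00097	gene00138	gene00100	gene00157	gene00114	gene00077	gene00045	gene00110
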