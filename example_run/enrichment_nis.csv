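set_name,es,nes,p_value,fdr_q,signed_q,tail,n_genes
set0006,0.8386219632577473,1.1041438879689125,0.08609271523178808,0.6716489412666475,0.6716489412666475,top,19
set0017,0.9060546951363315,1.155321235719634,0.0896551724137931,0.6716489412666475,0.6716489412666475,top,7
set0010,0.8479514354620924,1.110429010886137,0.12582781456953643,0.6716489412666475,0.6716489412666475,top,13
set0011,0.8306656402096846,1.0877925157735941,0.18543046357615894,0.6716489412666475,0.6716489412666475,top,13
set0013,0.8382615758533674,1.0834507265318964,0.19205298013245034,0.6716489412666475,0.6716489412666475,top,16
set0008,0.8161770320076311,1.0688190578583356,0.23841059602649006,0.6716489412666475,0.6716489412666475,top,13
set0018,0.8247593030612262,1.0699588518036012,0.25675675675675674,0.6716489412666475,0.6716489412666475,top,9
set0007,0.7901335052927903,1.044265136765317,0.2980132450331126,0.7414182062069385,0.7414182062069385,top,24
set0012,0.765806459992309,1.0244331842346586,0.3443708609271523,0.7414182062069385,0.7414182062069385,top,28
set0009,0.7905254199525341,1.0255472930278455,0.41216216216216217,0.7414182062069385,0.7414182062069385,top,9
set0016,0.7712245167589056,1.0192744265053924,0.41721854304635764,0.7414182062069385,0.7414182062069385,top,24
set0002,0.7570429548139372,0.975416244272045,0.5496688741721855,0.8637539522851395,0.8637539522851395,top,10
set0000,0.762096361968269,0.9749563297703158,0.609271523178808,0.8637539522851395,0.8637539522851395,top,14
set0014,0.7434554973821987,0.9479890436514059,0.6275862068965518,0.8856472166331322,0.8856472166331322,top,7
set0005,0.7359550561797747,0.9682755833209196,0.6490066225165563,0.8637539522851395,0.8637539522851395,top,20
set0003,0.6909776751606829,0.9177508951486079,0.7814569536423841,0.8856472166331322,0.8856472166331322,top,18
set0004,0.7030867575394104,0.9405319012672643,0.7880794701986755,0.8856472166331322,0.8856472166331322,top,28
set0001,0.6935483870967744,0.9092686802679034,0.8013245033112583,0.8856472166331322,0.8856472166331322,top,12
set0019,0.6976217854064259,0.898854705028908,0.8344370860927153,0.8856472166331322,0.8856472166331322,top,10
set0015,0.688524854845159,0.8871337137878557,0.8675496688741722,0.8856472166331322,0.8856472166331322,top,10
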