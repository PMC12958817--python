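set_name,es,nes,p_value,fdr_q,signed_q,tail,n_genes
set0019,0.8787993585498812,1.1336642134023915,0.09933774834437085,0.9188464118041583,0.9188464118041583,top,10
set0003,0.832873796396806,1.105766998399342,0.12582781456953643,0.9188464118041583,0.9188464118041583,top,18
set0004,0.7908235705201473,1.0708279416913542,0.152317880794702,0.9188464118041583,0.9188464118041583,top,28
set0007,0.815356631910283,1.0823198962209593,0.15894039735099338,0.9188464118041583,0.9188464118041583,top,24
set0006,0.7932960893854739,1.0569977930957937,0.23178807947019867,0.9188464118041583,0.9188464118041583,top,20
set0009,0.8077575294506948,1.052066916731746,0.34459459459459457,0.9188464118041583,0.9188464118041583,top,9
set0017,0.7916666666666661,1.0163493140171622,0.42758620689655175,0.9583426484834935,0.9583426484834935,top,7
set0011,0.7683648186806835,1.0086347262884179,0.4966887417218543,0.9583426484834935,0.9583426484834935,top,13
set0010,0.7594461897011701,0.9969272161566222,0.5364238410596026,0.9583426484834935,0.9583426484834935,top,13
set0000,0.768823128461305,0.9862093884171966,0.5695364238410596,0.9583426484834935,0.9583426484834935,top,14
set0016,0.7381453507263172,0.9798281734979479,0.5761589403973509,0.9583426484834935,0.9583426484834935,top,24
set0012,0.7132377905210234,0.9657716128235445,0.6821192052980133,0.9583426484834935,0.9583426484834935,top,28
set0015,0.733848897915751,0.9466759682035549,0.7152317880794702,0.9583426484834935,0.9583426484834935,top,10
set0001,0.7005347593582884,0.9220840600170953,0.7682119205298014,0.9583426484834935,0.9583426484834935,top,12
set0018,0.6892062618998585,0.8976593600338028,0.7905405405405406,0.9583426484834935,0.9583426484834935,top,9
set0002,0.703703703703702,0.9077882203328046,0.8079470198675497,0.9583426484834935,0.9583426484834935,top,10
set0008,0.7014915878459674,0.8998397215416225,0.847682119205298,0.9583426484834935,0.9583426484834935,top,14
set0013,0.6890018220182209,0.8903905816528159,0.9139072847682119,0.9583426484834935,0.9583426484834935,top,16
set0014,0.6458333333333337,0.8291270719613703,0.9241379310344827,0.9728370221327968,0.9728370221327968,top,7
set0005,0.6536312849162014,0.8709066323394933,0.9536423841059603,0.9654417734477038,0.9654417734477038,top,20
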