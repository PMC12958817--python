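set_name,es,nes,p_value,fdr_q,signed_q,tail,n_genes,category
set0017,-0.9309155207977695,-1.1866901237406091,0.1320754716981132,0.6734439093989656,-0.6734439093989656,WND,7,not-significant
set0005,-0.7771679161794759,-1.2858750952178477,0.13592233009708737,0.6734439093989656,-0.6734439093989656,WND,20,not-significant
set0010,-0.8568970635892199,-1.224253213405846,0.14432989690721648,0.6734439093989656,-0.6734439093989656,WND,13,not-significant
set0006,-0.7213688282156236,-1.1909091926382458,0.2523364485981308,0.6734439093989656,-0.6734439093989656,WND,19,not-significant
set0013,-0.7630983294543227,-1.1813625002762185,0.3142857142857143,0.6734439093989656,-0.6734439093989656,WND,15,not-significant
set0009,-0.8097631376526185,-1.1407504430206623,0.3191489361702128,0.6734439093989656,-0.6734439093989656,WND,9,not-significant
set0018,-0.803370900608977,-1.1317454057444962,0.3404255319148936,0.6734439093989656,-0.6734439093989656,WND,9,not-significant
set0001,-0.758897344194196,-1.1000945940265126,0.43478260869565216,0.700374531835206,-0.700374531835206,WND,12,not-significant
set0008,-0.726239595274285,-1.0375822207780636,0.4639175257731959,0.7472477584837136,-0.7472477584837136,WND,13,not-significant
set0016,-0.6184233129162304,-1.030774025608664,0.4672897196261682,0.7472477584837136,-0.7472477584837136,WND,24,not-significant
set0000,0.6429538981321956,0.989863415740845,0.4745762711864407,0.6208530805687204,0.6208530805687204,WPD,14,not-significant
set0011,-0.7098503990005155,-1.0141668923146205,0.4948453608247423,0.7472477584837136,-0.7472477584837136,WND,13,not-significant
set0002,0.6563307083222859,0.9703933290406342,0.5555555555555556,0.6208530805687204,0.6208530805687204,WPD,10,not-significant
set0019,0.6126897488500149,0.9058696134688354,0.6190476190476191,0.6208530805687204,0.6208530805687204,WPD,10,not-significant
set0007,-0.5413690815529943,-0.9023417712068591,0.6635514018691588,0.8295880149812734,-0.8295880149812734,WND,24,not-significant
set0004,0.46958903773826954,0.9053029782753412,0.6666666666666666,0.6208530805687204,0.6208530805687204,WPD,28,not-significant
set0012,-0.5350850999958452,-0.8813368097821048,0.7295081967213115,0.8295880149812734,-0.8295880149812734,WND,28,not-significant
set0003,-0.5247961246827793,-0.8164760224367305,0.7368421052631579,0.8295880149812734,-0.8295880149812734,WND,18,not-significant
set0015,-0.5493298346023315,-0.7644991701534536,0.8089887640449438,0.8295880149812734,-0.8295880149812734,WND,10,not-significant
set0014,-0.6275201140066338,-0.7999350156951832,0.8207547169811321,0.8295880149812734,-0.8295880149812734,WND,7,not-significant
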