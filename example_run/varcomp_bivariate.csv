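trait_1,trait_2,rg,rg_se,rp,loglik,converged,lrt_rg0_stat,lrt_rg0_p
CL_NIS,CL_IS,0.7111349921551965,,0.1043862832213187,-177.7632572396524,False,3.5928914548522357,0.05802719708701237
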