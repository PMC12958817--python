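trait,h2,h2_se,var_genetic,var_pen,var_residual,loglik,converged
CL_NIS,0.4111480969185138,0.16502330929529058,0.386251051247303,0.016636998763870786,0.5365570164799277,-87.83853076848682,True
CL_IS,0.3447591075323716,,0.3444988504500221,1.0686714090610334e-08,0.6547462434111543,-91.8146303365601,False
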