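cohort,quartile,lower,upper,controls,cases
breast_internal,1,-1.53,-0.58,75,2
breast_internal,2,-0.58,-0.28,74,5
breast_internal,3,-0.28,0.07,74,17
breast_internal,4,0.07,1.62,74,88
breast_external,1,-1.53,-0.58,58,8
breast_external,2,-0.58,-0.28,69,8
breast_external,3,-0.28,0.07,50,14
breast_external,4,0.07,1.62,48,83
ovarian,1,-1.53,-0.58,75,30
ovarian,2,-0.58,-0.28,74,31
ovarian,3,-0.28,0.07,74,51
ovarian,4,0.07,1.62,74,130
endometrial,1,-1.53,-0.58,75,39
endometrial,2,-0.58,-0.28,74,42
endometrial,3,-0.28,0.07,74,61
endometrial,4,0.07,1.62,74,75
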