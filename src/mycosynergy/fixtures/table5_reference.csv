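treatment,p_a,lc50,lower,upper,joint_toxicity,interaction
pinene,,3.41,,,,
conidia,,19.16,,,,
scheme_I,0.2,7.06,5.63,8.44,58,Antagonistic
scheme_II,0.4,4.2,3.16,5.07,121,Synergistic
scheme_III,0.6,2.4,2.02,2.74,280,Synergistic
scheme_IV,0.8,1.32,1.09,1.51,755,Synergistic
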