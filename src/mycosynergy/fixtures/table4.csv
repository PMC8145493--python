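treatment,component_a_conc,component_b_conc,total_conc,time_d,n_exposed,mortality_pct
pinene,0.7,0,0.7,2,250,8.4
pinene,1.4,0,1.4,2,250,12.4
pinene,2.1,0,2.1,2,250,23.6
pinene,2.8,0,2.8,2,250,27.6
pinene,3.5,0,3.5,2,250,31.6
pinene,0.7,0,0.7,4,250,12.4
pinene,1.4,0,1.4,4,250,21.6
pinene,2.1,0,2.1,4,250,28.8
pinene,2.8,0,2.8,4,250,42.4
pinene,3.5,0,3.5,4,250,56.8
pinene,0.7,0,0.7,6,250,24.4
pinene,1.4,0,1.4,6,250,32.4
pinene,2.1,0,2.1,6,250,49.2
pinene,2.8,0,2.8,6,250,63.2
pinene,3.5,0,3.5,6,250,79.6
scheme_I,0.14,3.2,3.34,2,250,19.6
scheme_I,0.28,6.4,6.68,2,250,24.4
scheme_I,0.42,9.6,10.02,2,250,28.0
scheme_I,0.56,12.8,13.36,2,250,29.2
scheme_I,0.7,16.0,16.7,2,250,32.8
scheme_I,0.14,3.2,3.34,4,250,36.4
scheme_I,0.28,6.4,6.68,4,250,43.2
scheme_I,0.42,9.6,10.02,4,250,54.4
scheme_I,0.56,12.8,13.36,4,250,65.6
scheme_I,0.7,16.0,16.7,4,250,76.4
scheme_I,0.14,3.2,3.34,6,250,66.4
scheme_I,0.28,6.4,6.68,6,250,72.4
scheme_I,0.42,9.6,10.02,6,250,77.6
scheme_I,0.56,12.8,13.36,6,250,83.6
scheme_I,0.7,16.0,16.7,6,250,87.6
scheme_II,0.28,2.4,2.68,2,250,21.6
scheme_II,0.56,4.8,5.36,2,250,23.6
scheme_II,0.84,7.2,8.04,2,250,28.4
scheme_II,1.12,9.6,10.72,2,250,31.6
scheme_II,1.4,12.0,13.4,2,250,34.8
scheme_II,0.28,2.4,2.68,4,250,41.6
scheme_II,0.56,4.8,5.36,4,250,43.2
scheme_II,0.84,7.2,8.04,4,250,61.2
scheme_II,1.12,9.6,10.72,4,250,77.6
scheme_II,1.4,12.0,13.4,4,250,81.6
scheme_II,0.28,2.4,2.68,6,250,70.4
scheme_II,0.56,4.8,5.36,6,250,80.8
scheme_II,0.84,7.2,8.04,6,250,84.4
scheme_II,1.12,9.6,10.72,6,250,89.6
scheme_II,1.4,12.0,13.4,6,250,92.8
scheme_III,0.42,1.6,2.02,2,250,23.6
scheme_III,0.84,3.2,4.04,2,250,27.6
scheme_III,1.26,4.8,6.06,2,250,34.4
scheme_III,1.68,6.4,8.08,2,250,38.4
scheme_III,2.1,8.0,10.1,2,250,40.4
scheme_III,0.42,1.6,2.02,4,250,46.6
scheme_III,0.84,3.2,4.04,4,250,71.2
scheme_III,1.26,4.8,6.06,4,250,87.2
scheme_III,1.68,6.4,8.08,4,250,97.6
scheme_III,2.1,8.0,10.1,4,250,98.8
scheme_III,0.42,1.6,2.02,6,250,77.2
scheme_III,0.84,3.2,4.04,6,250,87.6
scheme_III,1.26,4.8,6.06,6,250,96.4
scheme_III,1.68,6.4,8.08,6,250,98.8
scheme_III,2.1,8.0,10.1,6,250,99.2
scheme_IV,0.56,0.8,1.36,2,250,24.4
scheme_IV,1.12,1.6,2.72,2,250,29.6
scheme_IV,1.68,2.4,4.08,2,250,36.0
scheme_IV,2.24,3.2,5.44,2,250,42.8
scheme_IV,2.8,4.0,6.8,2,250,43.2
scheme_IV,0.56,0.8,1.36,4,250,51.6
scheme_IV,1.12,1.6,2.72,4,250,88.0
scheme_IV,1.68,2.4,4.08,4,250,94.8
scheme_IV,2.24,3.2,5.44,4,250,98.8
scheme_IV,2.8,4.0,6.8,4,250,99.2
scheme_IV,0.56,0.8,1.36,6,250,80.8
scheme_IV,1.12,1.6,2.72,6,250,96.8
scheme_IV,1.68,2.4,4.08,6,250,97.2
scheme_IV,2.24,3.2,5.44,6,250,98.8
scheme_IV,2.8,4.0,6.8,6,250,99.6
conidia,0,4.0,4.0,2,250,6.4
conidia,0,8.0,8.0,2,250,12.8
conidia,0,12.0,12.0,2,250,19.2
conidia,0,16.0,16.0,2,250,22.4
conidia,0,20.0,20.0,2,250,26.4
conidia,0,4.0,4.0,4,250,15.6
conidia,0,8.0,8.0,4,250,20.8
conidia,0,12.0,12.0,4,250,32.4
conidia,0,16.0,16.0,4,250,44.4
conidia,0,20.0,20.0,4,250,56.4
conidia,0,4.0,4.0,6,250,24.4
conidia,0,8.0,8.0,6,250,31.6
conidia,0,12.0,12.0,6,250,42.4
conidia,0,16.0,16.0,6,250,52.8
conidia,0,20.0,20.0,6,250,69.6
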