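# pressure_GPa: 0.0
# zpe_kJ_mol: 8.957499903873304
# z_molecules: 4
temperature_K,v_eq_A3_cell,g_kJ_mol,h_kJ_mol,s_J_K_mol,cp_J_K_mol,cv_J_K_mol,alpha_p_K,kappa_t_GPa
0.0,838.454511254647,8.95959697915805,8.95959697915805,0.0,0.0,0.0,0.0,0.0669142710058853
50.0,838.693069287433,8.797734607861116,9.135788038403948,6.761068610856638,5.880268007977918,5.872582981758437,9.239986505572805e-06,0.06702426985224245
100.0,839.1369964686115,8.333026915510061,9.483466337898605,11.504394223885441,7.810974748615251,7.7860374387588545,1.1571695004800899e-05,0.06719142447605776
150.0,839.6479404624497,7.669030057777093,9.904480354096012,14.903001975459462,8.953235736859355,8.90830818233259,1.2665070087325642e-05,0.06737165230342138
200.0,840.194211990624,6.854295445703656,10.373537074384895,17.596208143406194,9.771667416696772,9.705628492143966,1.3300629868160345e-05,0.06755828287682131
250.0,840.7624491693713,5.9166785587269715,10.878726981102993,19.84819368950409,10.412656642403206,10.324975916341199,1.3716629265985162e-05,0.06774896195674822
300.0,841.3457699965076,4.874519900079747,11.41290239533974,21.79460831753331,10.938842371552404,10.829253573352887,1.4010176024580608e-05,0.0679426101715263
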