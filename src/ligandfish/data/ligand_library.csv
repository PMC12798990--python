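id,rt,formula,detected_mw,par_mean,par_sd,name,source,quality_flag
C1,25.09,C19H18O7,358.1052,1.99,0.05,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone",reference_standard,
C2,23.81,C20H20O8,388.1157,1.83,0.18,5-Demethylnobiletin,reference_standard,
C3,7.98,C26H28O14,564.1478,1.69,0.15,Vicenin-3,reference_standard,
C4,9.92,C27H32O14,580.1789,1.68,0.01,Naringin,reference_standard,
C5,24.62,C21H22O9,418.1263,1.67,0.04,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone",reference_standard,
C6,20.93,C19H18O6,342.1102,1.62,0.16,"4′,5,6,7-Tetramethoxyflavone",reference_standard,
C7,22.82,C20H20O7,372.1206,1.61,0.21,Tangeretin,reference_standard,
C8,10.73,C28H34O15,610.1903,1.57,0.29,Neohesperidin,reference_standard,
C9,20.73,C21H22O8,402.1311,1.51,0.28,Nobiletin,reference_standard,
C10,20.0,C21H22O8,402.1313,1.47,0.07,"Quercetagetin-3,5,6,7,3′,4′-hexamethyl ether",reference_standard,
C11,18.69,C20H20O7,372.1207,1.41,0.23,Sinensetin,reference_standard,
C12,17.05,C20H20O7,372.1207,1.4,0.14,Isosinensetin,reference_standard,
C13,10.32,C28H34O15,610.1894,1.39,0.09,Hesperidin,reference_standard,
C14,10.03,C15H12O5,272.0685,1.35,0.09,Naringenin,reference_standard,
C15,10.06,C21H22O10,434.1213,1.32,0.03,Naringenin-7-O-glucoside,reference_standard,
C16,8.55,C27H32O15,596.1741,1.32,0.11,Eriocitrin,reference_standard,
C17,6.86,C27H30O15,594.1584,1.27,0.19,Vicenin-2,reference_standard,
C18,9.58,C27H30O14,578.1635,1.23,0.17,Rhoifolin,reference_standard,
C19,15.57,C16H14O6,302.079,1.19,0.08,Hesperetin,reference_standard,
C20,8.72,C21H20O12,464.0954,1.18,0.03,Isoquercitroside,reference_standard,
C21,23.72,C20H20O9,404.1107,2.31,0.02,"5,4´-Dihydroxy-3,6,7,8,3´-pentamethoxyflavone",literature,
C22,6.46,C27H32O15,596.1741,2.29,0.7,Eriocitrin isomer,literature,
C23,12.61,C19H18O7,358.1047,2.18,0.1,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C24,24.16,C20H20O8,388.1157,2.1,0.55,5-Demethylnobiletin isomer,literature,
C25,23.19,C19H18O7,358.1053,2.02,0.09,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C26,23.03,C20H22O7,374.1368,1.98,0.78,"2´-Hydroxy-3,4,4´,5´,6´-pentamethoxychalcone isomer",literature,
C27,16.18,C20H22O7,374.1365,1.37,0.02,"2´-Hydroxy-3,4,4´,5´,6´-pentamethoxychalcone isomer",literature,
C28,9.93,C28H34O15,610.1903,1.92,0.2,Neohesperidin isomer/Hesperidin isomer,literature,
C29,22.32,C19H18O7,358.1053,1.79,0.07,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C30,19.38,C20H22O7,374.1366,1.76,0.1,"2´-Hydroxy-3,4,4´,5´,6´-pentamethoxychalcone",literature,
C31,7.18,C15H12O5,272.0684,1.75,0.23,Naringenin isomer,literature,
C32,8.43,C21H20O12,464.0955,1.74,0.17,Isoquercitroside isomer,literature,
C33,8.55,C21H22O10,434.1213,1.74,0.11,Naringenin-7-O-glucoside isomer,literature,
C34,10.17,C15H12O5,272.0684,1.73,0.12,Naringenin isomer,literature,
C35,14.16,C21H22O9,418.1264,1.69,0.05,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone isomer",literature,
C36,9.1,C27H30O14,578.0,1.69,0.24,Rhoifolin isomer,literature,detected_mw_placeholder
C37,23.48,C20H20O8,388.1158,1.65,0.04,5-Demethylnobiletin isomer,literature,
C38,10.72,C16H14O6,302.079,1.64,0.22,Hesperetin isomer,literature,
C39,21.06,C19H18O8,374.1001,1.63,0.34,"Quercetagetin-3,7,3′,4′-tetramethyl ether",literature,
C40,16.79,C20H20O8,388.1158,1.58,0.21,5-Demethylnobiletin isomer,literature,
C41,19.03,C18H16O7,344.0896,1.58,0.06,Dihydroxy-trimethoxyflavone isomer,literature,
C42,8.41,C27H30O14,578.0,1.57,0.31,Rhoifolin isomer,literature,detected_mw_placeholder
C43,15.81,C21H22O9,418.1264,1.57,0.15,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone isomer",literature,
C44,8.41,C26H28O14,564.1478,1.55,0.17,Vicenin-3 isomer,literature,
C45,8.51,C15H12O5,272.0684,1.53,0.24,Naringenin isomer,literature,
C46,22.39,C20H20O9,404.1107,1.53,0.06,"5,4´-Dihydroxy-3,6,7,8,3´-pentamethoxyflavone isomer",literature,
C47,9.26,C27H30O15,594.1585,1.53,0.14,Kaempferol-3-O-rutinoside isomer,literature,
C48,22.09,C20H20O9,404.1107,1.52,0.16,"5,4´-dihydroxy-3,6,7,8,3´-pentamethoxyflavone isomer",literature,
C49,20.41,C18H16O7,344.0896,1.52,0.08,Dihydroxy-trimethoxyflavone isomer,literature,
C50,8.26,C28H34O15,610.1899,1.5,0.18,Neohesperidin isomer/Hesperidin isomer,literature,
C51,15.97,C20H20O8,388.1157,1.49,0.04,5-Demethylnobiletin isomer,literature,
C52,17.79,C21H22O9,418.1263,1.49,0.09,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone isomer",literature,
C53,12.02,C27H30O14,578.0,1.48,0.26,Rhoifolin isomer,literature,detected_mw_placeholder
C54,7.3,C27H32O15,596.1741,1.48,0.21,Eriocitrin isomer,literature,
C55,15.2,C27H32O14,580.1792,1.46,0.13,Naringin isomer,literature,
C56,14.97,C19H18O7,358.1052,1.46,0.26,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C57,22.02,C22H24O9,432.1416,1.45,0.08,"3,3′,4′,5,6,7,8-heptamethoxyflavone",literature,
C58,18.59,C21H22O9,418.1263,1.45,0.07,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone isomer",literature,
C59,23.93,C21H22O8,402.1313,1.44,0.18,"Quercetagetin-3,5,6,7,3′,4′-hexamethyl ether isomer/Nobiletin isomer",literature,
C60,8.64,C27H30O15,594.1585,1.44,0.09,Kaempferol-3-O-rutinoside,literature,
C61,19.33,C20H20O7,372.121,1.42,0.09,Tangeretin isomer/Isosinensetin isomer/Sinensetin isomer,literature,
C62,8.25,C26H28O14,564.1479,1.41,0.16,Vicenin-3 isomer,literature,
C63,8.26,C16H14O6,302.079,1.39,0.2,Hesperetin isomer,literature,
C64,17.59,C20H20O8,388.1157,1.39,0.21,5-Demethylnobiletin isomer,literature,
C65,19.02,C19H18O7,358.1053,1.39,0.2,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C66,9.56,C21H22O10,434.1212,1.38,0.18,Naringenin-7-O-glucoside isomer,literature,
C67,20.06,C18H16O7,344.0896,1.38,0.04,Dihydroxy-trimethoxyflavone isomer,literature,
C68,18.19,C21H22O8,402.1313,1.37,0.25,"Quercetagetin-3,5,6,7,3′,4′-hexamethyl ether isomer/Nobiletin isomer",literature,
C69,20.7,C20H20O7,372.124,1.37,0.02,Tangeretin isomer/Isosinensetin isomer/Sinensetin isomer,literature,detected_mw_outlier
C70,16.0,C19H18O7,358.1052,1.36,0.28,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C71,9.57,C27H32O14,580.1789,1.35,0.16,Naringin isomer,literature,
C72,14.14,C19H18O7,358.1053,1.35,0.02,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,par_printed_135
C73,10.3,C27H32O15,596.1741,1.35,0.1,Eriocitrin isomer,literature,
C74,18.15,C19H18O6,342.1103,1.35,0.17,"4′,5,6,7-Tetramethoxyflavone isomer",literature,
C75,10.32,C16H14O6,302.079,1.34,0.07,Hesperetin isomer,literature,
C76,17.05,C19H18O7,358.1047,1.34,0.06,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C77,9.57,C15H12O5,272.0684,1.33,0.17,Naringenin isomer,literature,
C78,10.31,C18H16O7,344.0896,1.28,0.05,Dihydroxy-trimethoxyflavone,literature,
C79,19.12,C19H18O6,342.1101,1.27,0.14,"4′,5,6,7-Tetramethoxyflavone isomer",literature,
C80,7.39,C27H32O14,580.179,1.25,0.2,Naringin isomer,literature,
C81,7.39,C21H22O10,434.1213,1.25,0.15,Naringenin-7-O-glucoside isomer,literature,
C82,14.53,C19H18O7,358.1053,1.24,0.09,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone isomer",literature,
C83,8.25,C15H12O5,272.0684,1.19,0.14,Naringenin isomer,literature,
C84,7.39,C15H12O5,272.0685,1.15,0.1,Naringenin isomer,literature,
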