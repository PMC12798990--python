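id,name,formula,rt
C1,"5-Hydroxy-3,7,3’,4’-tetramethoxyflavone",C19H18O7,25.09
C2,5-Demethylnobiletin,C20H20O8,23.81
C3,Vicenin-3,C26H28O14,7.98
C4,Naringin,C27H32O14,9.92
C5,"8-Hydroxy-3,5,6,7,3′,4′-hexamethoxyflavone",C21H22O9,24.62
C6,"4′,5,6,7-Tetramethoxyflavone",C19H18O6,20.93
C7,Tangeretin,C20H20O7,22.82
C8,Neohesperidin,C28H34O15,10.73
C9,Nobiletin,C21H22O8,20.73
C10,"Quercetagetin-3,5,6,7,3′,4′-hexamethyl ether",C21H22O8,20.0
C11,Sinensetin,C20H20O7,18.69
C12,Isosinensetin,C20H20O7,17.05
C13,Hesperidin,C28H34O15,10.32
C14,Naringenin,C15H12O5,10.03
C15,Naringenin-7-O-glucoside,C21H22O10,10.06
C16,Eriocitrin,C27H32O15,8.55
C17,Vicenin-2,C27H30O15,6.86
C18,Rhoifolin,C27H30O14,9.58
C19,Hesperetin,C16H14O6,15.57
C20,Isoquercitroside,C21H20O12,8.72
C21,"5,4´-Dihydroxy-3,6,7,8,3´-pentamethoxyflavone",C20H20O9,23.72
C30,"2´-Hydroxy-3,4,4´,5´,6´-pentamethoxychalcone",C20H22O7,19.38
C39,"Quercetagetin-3,7,3′,4′-tetramethyl ether",C19H18O8,21.06
C57,"3,3′,4′,5,6,7,8-heptamethoxyflavone",C22H24O9,22.02
C60,Kaempferol-3-O-rutinoside,C27H30O15,8.64
C78,Dihydroxy-trimethoxyflavone,C18H16O7,10.31
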