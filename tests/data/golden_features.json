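{
 "RV_75-25": 0.13831617778029526,
 "RV_DYN": -0.03279535502380951,
 "RV_NA2": 15.006439342357769,
 "RV_ND1": 1.162504488016161,
 "RV_ND2": 0.7723514742888646,
 "RV_P10": 0.8316084589968449,
 "RV_P25": 0.8953058012556145,
 "RV_P50": 0.962900483946498,
 "RV_P75": 1.0336219790359098,
 "RV_P90": 1.10552836705332,
 "RV_SAMPEN": 1.7553003714012565,
 "RV_SD": 0.10692969132936242,
 "RV_VAR": 0.011433958887792726,
 "XCORR_XY": 0.044987228906278195,
 "XCORR_XZ": 0.01255000479028098,
 "XCORR_YZ": 0.091920402519204,
 "X_75-25": 0.2575723258257602,
 "X_DYN": -0.03525930042300234,
 "X_NA2": 1.6143947283751743,
 "X_ND1": 2.1791198265360605,
 "X_ND2": 1.3172247409476363,
 "X_P10": -0.2576750364223591,
 "X_P25": -0.14836732097237548,
 "X_P50": -0.007284569550385482,
 "X_P75": 0.10920500485338468,
 "X_P90": 0.22598397424022812,
 "X_SAMPEN": 1.7381242533954235,
 "X_SD": 0.19469035648194144,
 "X_VAR": 0.03790433490706544,
 "Y_75-25": 0.2925938267505176,
 "Y_DYN": 0.08259055778539555,
 "Y_NA2": 3.8572766702562244,
 "Y_ND1": 2.226864702246797,
 "Y_ND2": 1.3295655700931552,
 "Y_P10": -0.053313192408260594,
 "Y_P25": 0.06331926959839837,
 "Y_P50": 0.19579338368481694,
 "Y_P75": 0.355913096348916,
 "Y_P90": 0.49615526811171357,
 "Y_SAMPEN": 1.6557186649981066,
 "Y_SD": 0.21434818068552416,
 "Y_VAR": 0.04594514256319411,
 "Z_75-25": 0.12980358015179683,
 "Z_DYN": -0.16151459389690137,
 "Z_NA2": 13.95770571520884,
 "Z_ND1": 1.1103166002551677,
 "Z_ND2": 0.629002815109592,
 "Z_P10": 0.7864599132087959,
 "Z_P25": 0.833886448120278,
 "Z_P50": 0.8990331804910761,
 "Z_P75": 0.9636900282720748,
 "Z_P90": 1.0246389216605913,
 "Z_SAMPEN": 1.8067973465925955,
 "Z_SD": 0.09272307890196094,
 "Z_VAR": 0.008597569361059274
}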