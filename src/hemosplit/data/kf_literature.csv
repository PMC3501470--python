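study,method,subject,stimulation,duration,k_f
Jasdzewski,CW,human,visual pattern reversal,2 s,-0.36
Tang,CW,human,visual pattern reversal,4 s,-0.37
McIntosh,FDMD,human,visual pattern reversal,30 s,-0.40
Siegel,DOT,rat,forepaw stimulation,6 s,-0.48
Siegel,DOT,rat,forepaw stimulation,30 s,-0.48
Villringer,CW,human,flash light exposure,50 s,-0.51
Lindauer,CW,rat,whisker deflection,4 s,-0.53
Obrig,CW,human,visual pattern reversal,30 s,-0.56
Zeff,DOT,human,visual pattern reversal,10 s,-0.56
Boden,CW,human,alternating finger tapping,20 s,-0.57
Dunn,OIS,rat,forepaw stimulation,10 s,-0.57
Colier,CW,human,visual pattern reversal,10 s,-0.61
Berwick,OIS,rat,whisker stimulation,1 s,-0.63
Yamada,CWMD,human,finger tapping,20 s,-0.66
Huppert,CW,rat,whisker stimulation,20 ms,-0.66
Franceschini,CW,human,finger tactile,20 s,-0.67
Sheth,CW,rat,hind-paw stimulation,2 s,-0.82
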