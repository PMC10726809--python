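tissue,gene,ddct,fold_change_printed,significant
flight_muscle,ATF-4,-0.781,1.718,0
flight_muscle,Drp,-1.575,2.98,1
flight_muscle,Marf,-1.764,3.397,1
flight_muscle,Opa1,-2.388,5.235,1
flight_muscle,Dmic60 (mitofilin),0.244,0.844,0
flight_muscle,CHCHD3/6 (mic19),-2.279,4.853,1
flight_muscle,MINOS1 (Mic10),-0.385,1.306,0
flight_muscle,QIL1 (Mic13),-1.549,2.926,1
flight_muscle,APOO (mic26/27),-1.053,2.075,1
flight_muscle,IP3R/Itpr,-0.997,1.996,1
flight_muscle,VDAC/porin,-3.265,9.612,1
flight_muscle,FGF21/bln,-0.14,1.102,0
flight_muscle,ATF-6,0.072,0.952,0
flight_muscle,Bip(grp78)/Hsc 70-3,-2.259,4.786,1
flight_muscle,GRP75/Hsc70-5,-1.203,2.301,0
flight_muscle,Ire1,-1.219,2.328,0
cardiac,ATF-4,-0.595,1.51,1
cardiac,Drp,0.01,0.993,0
cardiac,Marf,0.032,0.978,0
cardiac,Opa1,-0.428,1.346,0
cardiac,MINOS1 (Mic10),-0.452,1.368,0
cardiac,QIL1 (Mic13),0.012,0.992,0
cardiac,CHCHD3/6 (mic19),0.123,0.918,0
cardiac,Dmic60 (mitofilin),-1.791,3.46,1
cardiac,APOO (mic26/27),-0.012,1.008,0
cardiac,VDAC/Porin,0.29,0.818,0
cardiac,IP3R/Itpr,0.243,0.845,0
cardiac,FGF21/bln,0.927,0.526,1
cardiac,Ire1,0.221,0.858,0
cardiac,Bip(grp78)/Hsc 70-3,-0.223,1.167,0
cardiac,ATF-6,0.141,0.907,0
cardiac,GRP75/Hsc70-5,-0.224,1.168,0
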