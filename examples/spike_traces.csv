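trace_id,time_s,stress_Pa
trace0,0.0,10.0
trace0,0.004166666666666667,51.480759674514424
trace0,0.008333333333333333,92.96151934902885
trace0,0.0125,134.44227902354328
trace0,0.015,159.3307348282519
trace0,0.016666666666666666,152.219747455478
trace0,0.020833333333333332,134.44227902354325
trace0,0.025,116.6648105916085
trace0,0.029166666666666667,98.88734215967375
trace0,0.03333333333333333,81.109873727739
trace0,0.0375,63.332405295804264
trace0,0.041666666666666664,45.554936863869514
trace0,0.04583333333333333,27.77746843193478
trace0,0.05,27.77746843193478
trace1,0.0,10.0
trace1,0.004166666666666667,41.13326502769003
trace1,0.008333333333333333,72.26653005538006
trace1,0.0125,103.39979508307007
trace1,0.015,122.07975409968408
trace1,0.016666666666666666,116.74262295208008
trace1,0.020833333333333332,103.39979508307007
trace1,0.025,90.05696721406005
trace1,0.029166666666666667,76.71413934505006
trace1,0.03333333333333333,63.37131147604005
trace1,0.0375,50.02848360703004
trace1,0.041666666666666664,36.68565573802003
trace1,0.04583333333333333,23.342827869010023
trace1,0.05,23.342827869010023
trace2,0.0,10.0
trace2,0.004166666666666667,55.565271581220145
trace2,0.008333333333333333,101.13054316244029
trace2,0.0125,146.69581474366043
trace2,0.015,174.03497769239252
trace2,0.016666666666666666,166.22378827846907
trace2,0.020833333333333332,146.69581474366043
trace2,0.025,127.1678412088518
trace2,0.029166666666666667,107.63986767404316
trace2,0.03333333333333333,88.11189413923454
trace2,0.0375,68.58392060442591
trace2,0.041666666666666664,49.05594706961729
trace2,0.04583333333333333,29.527973534808638
trace2,0.05,29.527973534808638
trace3,0.0,10.0
trace3,0.004166666666666667,57.42011025337883
trace3,0.008333333333333333,104.84022050675766
trace3,0.0125,152.2603307601365
trace3,0.015,180.7123969121638
trace3,0.016666666666666666,172.58323515444172
trace3,0.020833333333333332,152.2603307601365
trace3,0.025,131.93742636583127
trace3,0.029166666666666667,111.61452197152607
trace3,0.03333333333333333,91.29161757722086
trace3,0.0375,70.96871318291565
trace3,0.041666666666666664,50.64580878861045
trace3,0.04583333333333333,30.322904394305255
trace3,0.05,30.322904394305255
trace4,0.0,10.0
trace4,0.004166666666666667,35.53502639928785
trace4,0.008333333333333333,61.0700527985757
trace4,0.0125,86.60507919786355
trace4,0.015,101.92609503743626
trace4,0.016666666666666666,97.54866194041549
trace4,0.020833333333333332,86.60507919786355
trace4,0.025,75.6614964553116
trace4,0.029166666666666667,64.71791371275967
trace4,0.03333333333333333,53.77433097020775
trace4,0.0375,42.83074822765582
trace4,0.041666666666666664,31.88716548510388
trace4,0.04583333333333333,20.943582742551953
trace4,0.05,20.943582742551953
trace5,0.0,10.0
trace5,0.004166666666666667,39.417344329820864
trace5,0.008333333333333333,68.83468865964173
trace5,0.0125,98.25203298946262
trace5,0.015,115.90243958735512
trace5,0.016666666666666666,110.85946627367154
trace5,0.020833333333333332,98.2520329894626
trace5,0.025,85.64459970525365
trace5,0.029166666666666667,73.0371664210447
trace5,0.03333333333333333,60.42973313683577
trace5,0.0375,47.82229985262684
trace5,0.041666666666666664,35.214866568417904
trace5,0.04583333333333333,22.607433284208966
trace5,0.05,22.607433284208966
trace6,0.0,10.0
trace6,0.004166666666666667,49.95726439160271
trace6,0.008333333333333333,89.91452878320543
trace6,0.0125,129.87179317480815
trace6,0.015,153.84615180976976
trace6,0.016666666666666666,146.99633505692358
trace6,0.020833333333333332,129.87179317480815
trace6,0.025,112.74725129269268
trace6,0.029166666666666667,95.62270941057724
trace6,0.03333333333333333,78.4981675284618
trace6,0.0375,61.37362564634637
trace6,0.041666666666666664,44.24908376423092
trace6,0.04583333333333333,27.12454188211548
trace6,0.05,27.12454188211548
trace7,0.0,10.0
trace7,0.004166666666666667,46.35936932577244
trace7,0.008333333333333333,82.71873865154488
trace7,0.0125,119.07810797731733
trace7,0.015,140.89372957278079
trace7,0.016666666666666666,134.66069483121979
trace7,0.020833333333333332,119.07810797731733
trace7,0.025,103.49552112341485
trace7,0.029166666666666667,87.91293426951236
trace7,0.03333333333333333,72.3303474156099
trace7,0.0375,56.74776056170744
trace7,0.041666666666666664,41.16517370780497
trace7,0.04583333333333333,25.582586853902498
trace7,0.05,25.582586853902498
trace8,0.0,10.0
trace8,0.004166666666666667,48.75048019110787
trace8,0.008333333333333333,87.50096038221574
trace8,0.0125,126.25144057332359
trace8,0.015,149.5017286879883
trace8,0.016666666666666666,142.85878922665552
trace8,0.020833333333333332,126.25144057332359
trace8,0.025,109.64409191999164
trace8,0.029166666666666667,93.0367432666597
trace8,0.03333333333333333,76.42939461332777
trace8,0.0375,59.82204595999583
trace8,0.041666666666666664,43.21469730666389
trace8,0.04583333333333333,26.607348653331954
trace8,0.05,26.607348653331954
trace9,0.0,10.0
trace9,0.004166666666666667,42.41225040294853
trace9,0.008333333333333333,74.82450080589706
trace9,0.0125,107.2367512088456
trace9,0.015,126.68410145061472
trace9,0.016666666666666666,121.12771566725212
trace9,0.020833333333333332,107.2367512088456
trace9,0.025,93.34578675043909
trace9,0.029166666666666667,79.45482229203257
trace9,0.03333333333333333,65.56385783362606
trace9,0.0375,51.672893375219545
trace9,0.041666666666666664,37.781928916813044
trace9,0.04583333333333333,23.89096445840653
trace9,0.05,23.89096445840653
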