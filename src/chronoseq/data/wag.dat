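# WAG amino-acid replacement model: Whelan & Goldman (2001)
# Lower-triangle symmetric exchangeabilities, then equilibrium frequencies.
# State order: A R N D C Q E G H I L K M F P S T W Y V
0.551571
0.509848 0.635346
0.738998 0.147304 5.429420
1.0270400 0.5281910 0.2652560 0.0302949
0.9085980 3.0355000 1.5436400 0.6167830 0.0988179
1.582850 0.439157 0.947198 6.174160 0.021352 5.469470
1.416720 0.584665 1.125560 0.865584 0.306674 0.330052 0.567717
0.316954 2.137150 3.956290 0.930676 0.248972 4.294110 0.570025 0.249410
0.1933350 0.1869790 0.5542360 0.0394370 0.1701350 0.1139170 0.1273950 0.0304501 0.1381900
0.3979150 0.4976710 0.1315280 0.0848047 0.3842870 0.8694890 0.1542630 0.0613037 0.4994620 3.1709700
0.9062650 5.3514200 3.0120100 0.4798550 0.0740339 3.8949000 2.5844300 0.3735580 0.8904320 0.3238320 0.2575550
0.893496 0.683162 0.198221 0.103754 0.390482 1.545260 0.315124 0.174100 0.404141 4.257460 4.854020 0.934276
0.2104940 0.1027110 0.0961621 0.0467304 0.3980200 0.0999208 0.0811339 0.0499310 0.6793710 1.0594700 2.1151700 0.0888360 1.1906300
1.4385500 0.6794890 0.1950810 0.4239840 0.1094040 0.9333720 0.6823550 0.2435700 0.6961980 0.0999288 0.4158440 0.5568960 0.1713290 0.1614440
3.370790 1.224190 3.974230 1.071760 1.407660 1.028870 0.704939 1.341820 0.740169 0.319440 0.344739 0.967130 0.493905 0.545931 1.613280
2.121110 0.554413 2.030060 0.374866 0.512984 0.857928 0.822765 0.225833 0.473307 1.458160 0.326622 1.386980 1.516120 0.171903 0.795384 4.378020
0.1131330 1.1639200 0.0719167 0.1297670 0.7170700 0.2157370 0.1565570 0.3369830 0.2625690 0.2124830 0.6653090 0.1375050 0.5157060 1.5296400 0.1394050 0.5237420 0.1108640
0.240735 0.381533 1.086000 0.325711 0.543833 0.227710 0.196303 0.103604 3.873440 0.420170 0.398618 0.133264 0.428437 6.454280 0.216046 0.786993 0.291148 2.485390
2.006010 0.251849 0.196246 0.152335 1.002140 0.301281 0.588731 0.187247 0.118358 7.821300 1.800340 0.305434 2.058450 0.649892 0.314887 0.232739 1.388230 0.365369 0.314730
0.08662790866 0.04397200440 0.03908940391 0.05704510570 0.01930780193 0.03672810367 0.05805890581 0.08325180833 0.02443130244 0.04846600485 0.08620900862 0.06202860620 0.01950270195 0.03843190384 0.04576310458 0.06951790695 0.06101270610 0.01438590144 0.03527420353 0.07089560709
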