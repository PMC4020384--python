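# BLOSUM62 amino-acid replacement model: Henikoff & Henikoff (1992)
# Lower-triangle symmetric exchangeabilities, then equilibrium frequencies.
# State order: A R N D C Q E G H I L K M F P S T W Y V
0.7357903897
0.4853910555 1.2974467051
0.5431618209 0.5009644086 3.1801000482
1.4599953105 0.2278265742 0.3973589499 0.2408366148
1.1997057046 3.0208336101 1.8392161470 1.1909457034 0.3298015046
1.1709490428 1.3605741904 1.2404885086 3.7616252084 0.1407488918 5.5289191779
1.9558835750 0.4187633085 1.3558723445 0.7984732490 0.4182031923 0.6098463054 0.4235799922
0.7162414450 1.4561411663 2.4145014342 0.7781426640 0.3540581098 2.4353411311 1.6268910570 0.5398591250
0.6058990037 0.2320364451 0.2830173263 0.4185557325 0.7748940228 0.2362024512 0.1868480469 0.1892962924 0.2527184479
0.8000165305 0.6227116697 0.2118881596 0.2181315776 0.8318426401 0.5807370932 0.3726251751 0.2177211592 0.3480722098 3.8909637733
1.2952012668 5.4111151415 1.5931370435 1.0324479250 0.2850788009 3.9452776745 2.8024271517 0.7520424403 1.0225070359 0.4061935866 0.4455702743
1.2537582667 0.9836929875 0.6484412788 0.2226218980 0.7676888235 2.4948960771 0.5554153975 0.4594361736 0.9843115254 3.3647977631 6.0305593796 1.0730611843
0.4929646797 0.3716446932 0.3548612492 0.2817306942 0.4413374712 0.1443569598 0.2914090842 0.3681664645 0.7145337039 1.5173593260 2.0648397032 0.2669247505 1.7738551688
1.1732759009 0.4481336617 0.4948870437 0.7306282730 0.3560084988 0.8585705757 0.9265639348 0.5040865995 0.5270073392 0.3883554092 0.3745556875 1.0473834507 0.4541236251 0.2335979096
4.3250926871 1.1227831042 2.9041016565 1.5827541421 1.1971884151 1.9348709246 1.7698932389 1.5093262532 1.1170297629 0.3575444125 0.3529691845 1.7521659178 0.9187234157 0.5400276448 1.1691295777
1.7291780195 0.9146659546 1.8981736345 0.9341875094 1.1198313585 1.2774802946 1.0710972360 0.6414360114 0.5854070902 1.1790911973 0.9152598577 1.3038752008 1.4885480537 0.4882061188 1.0054516831 5.1515562923
0.4658393677 0.4263823101 0.1914820462 0.1453450463 0.5276644189 0.7586538086 0.4076356489 0.5083589246 0.3012486008 0.3419857875 0.6914746346 0.3322430406 0.8881010982 2.0743248935 0.2522148300 0.3879256221 0.5131281269
0.7182066976 0.7205174412 0.5382225190 0.2614222090 0.4702377337 0.9589897429 0.5967193003 0.3080557370 4.2189539694 0.6746170932 0.8112458563 0.7179934869 0.9516821622 6.7472604308 0.3694053194 0.7967515208 0.8010102432 4.0544190066
2.1877745220 0.4383883438 0.3128587980 0.2581292894 1.1163524786 0.5307857901 0.5242538463 0.2533407902 0.2015559718 8.3118394055 2.2314056889 0.4981384753 2.5758507553 0.8381196102 0.4969084107 0.5619254574 2.2530740512 0.2665087314 1.0000000000
0.074 0.052 0.045 0.054 0.025 0.034 0.054 0.074 0.026 0.068 0.099 0.058 0.025 0.047 0.039 0.057 0.051 0.013 0.032 0.073
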