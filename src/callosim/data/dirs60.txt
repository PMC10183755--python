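0.1260923990 -0.0987734596 0.9870889071
-0.1132657977 0.1309809559 0.9848933182
-0.2059204444 -0.2120916767 0.9553082703
0.2207632430 0.2558258435 0.9411783722
-0.4322130247 0.0262116722 0.9013905089
0.0377045632 -0.4384380372 0.8979701852
0.4400029571 0.0312174011 0.8974535485
-0.0344336003 0.4523229886 0.8911892286
0.3562379507 -0.3214936946 0.8773461842
-0.3600244168 0.3588652564 0.8611609298
-0.2915156610 -0.5071785011 0.8110416681
-0.5447077233 -0.2559384355 0.7986169378
0.3171536523 0.5443729353 0.7765768913
0.5595648391 0.3175312651 0.7655462667
0.6359622858 -0.1724834619 0.7521977309
-0.6434822098 0.2114057812 0.7356889570
0.2908209562 -0.6182728718 0.7301793118
-0.2847859353 0.6466285842 0.7076499453
0.0446050401 0.7113226122 0.7014488803
-0.0340904843 -0.7156044776 0.6976733265
0.6000877386 -0.4738033116 0.6445192999
-0.7656485669 -0.0734551490 0.6390513384
0.7664535176 0.0986064446 0.6346855714
-0.5816458905 -0.5205083408 0.6251072910
-0.5850464558 0.5271350383 0.6163191511
-0.3404377368 -0.7534109396 0.5625603110
0.5734285608 0.5970646977 0.5609754294
0.2774849338 0.8138993085 0.5104606029
0.8406288875 -0.2257942748 0.4923007404
-0.8204264311 0.3103639311 0.4801819462
0.2083703449 -0.8523638847 0.4796432084
-0.1333242570 0.8707821063 0.4732474678
0.8020902296 0.3720948526 0.4671152793
-0.8089699234 -0.3569476965 0.4670717344
0.5012321759 -0.7295045269 0.4653917178
-0.4490913644 0.7825004840 0.4312886955
-0.0815438285 -0.9162255395 0.3922771530
-0.9291316915 0.0204553417 0.3691827174
-0.6326802049 -0.6881968790 0.3551067643
0.7744688845 -0.5277840499 0.3487720511
0.9402515486 0.0568192427 0.3357061200
-0.7378449672 0.5982217065 0.3125949363
0.5168884114 0.8005710392 0.3031705485
0.0917978155 0.9595632224 0.2661044595
-0.3723889642 -0.8936476870 0.2504401541
0.7702580350 0.5970983038 0.2240003909
-0.9491757158 -0.2478022757 0.1940605389
0.9426061653 -0.2831558095 0.1769644163
0.3054424727 -0.9362522371 0.1735990908
0.6056862531 -0.7773176065 0.1700632279
-0.9360749073 0.3091825811 0.1678389093
-0.2417693758 0.9578349580 0.1552409810
0.9362288907 0.3230476464 0.1382594751
-0.8306718985 -0.5403875566 0.1340353898
-0.5489319537 0.8256867243 0.1300582313
-0.0171497251 -0.9964455466 0.0824752059
0.3296373145 0.9418127297 0.0657877116
-0.6227372144 -0.7820134557 0.0255600659
0.8194271382 -0.5731504290 0.0061441795
0.9999375923 -0.0111591260 0.0005342904
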