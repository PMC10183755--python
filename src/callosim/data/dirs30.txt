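-0.0057393489 -0.1640099148 0.9864419941
0.1704077306 0.2842516350 0.9434840822
-0.3111658703 0.3022591477 0.9010078850
-0.4431371933 -0.1368453975 0.8859473828
0.4406543084 -0.1475541341 0.8854668588
0.1913777405 -0.5845813957 0.7884409631
-0.2733631165 -0.5686222209 0.7758488103
-0.0658871103 0.6626625539 0.7460142280
0.6157153830 0.2648647018 0.7421194357
-0.7446401775 0.1384038316 0.6529589462
0.4111270804 0.6421359184 0.6470208544
0.6108534581 -0.4989240072 0.6147624645
-0.7128623519 -0.3776907028 0.5909120072
-0.5816049653 0.5653361502 0.5849193975
0.8334603031 -0.0939310315 0.5445373124
-0.0314718333 -0.8765266265 0.4803234293
-0.5271761053 -0.7492399801 0.4009049842
-0.3068053899 0.8668439176 0.3930039125
0.1580238844 0.9163936413 0.3677650693
0.4431890367 -0.8230833346 0.3551299791
0.8565021503 0.3804683348 0.3487806083
-0.9482624825 -0.1103702301 0.2976855330
-0.8916927746 0.3775239044 0.2497192369
0.6129327372 0.7573190554 0.2253470831
0.8525870575 -0.4775551640 0.2122177532
0.9928010684 -0.0130473651 0.1190621886
-0.8421349730 -0.5279617575 0.1098411124
-0.6379429059 0.7651018047 0.0874532863
-0.3109568099 -0.9473426825 0.0764702834
0.1608208410 -0.9863710597 0.0347676532
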