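x,n,lower,upper
 54,  56,0.8661899729327281472,0.993789861573669109
 54, 261,0.1604536813830858277,0.262170008815580946
149, 151,0.9480449580064406190,0.997702542052537722
  0,  10,0.0000000000000000000,0.344537218306922466
 10,  10,0.6554627816930774786,1.000000000000000000
  1,   2,0.0945312057342307388,0.905468794265769206
  5,1000,0.0018422221114653341,0.012343325193068020
 28,  30,0.7649271312982367510,0.988368162491248814
 97, 304,0.2676648662509572008,0.375149061015930652
 67,  72,0.8386409257429798814,0.974152549287478076
 93, 288,0.2699120593513514854,0.380731850495469037
 56, 360,0.1205340104110703969,0.198117554485301439
 71,  72,0.9146185424962426369,0.999274571222065422
151, 360,0.3682318103900352746,0.472404194097563901
  2,  56,0.0062101384263311054,0.133810027067271853
313, 403,0.7322012741997350194,0.815765447892266793
 35, 140,0.1824527707174692370,0.331553393361407100
145, 328,0.3878178544359605073,0.497707445650712177
 91, 113,0.7179119538066764949,0.871446695671606930
  3, 201,0.0038625555428973717,0.046532149105802126
177, 230,0.7086695532819127230,0.821254560469637296
214, 359,0.5431792746362331670,0.646930897023396678
244, 437,0.5103393658485918527,0.605323601976740511
113, 414,0.2311318633141527801,0.319053539640937023
129, 266,0.4236998892646864912,0.546666376917441466
  2, 376,0.0009218558344862213,0.021213845128775305
257, 378,0.6298972992800710990,0.726170247273662195
185, 362,0.4583408875398370386,0.563520316802425092
 39, 142,0.2047565942744118128,0.356970714564823211
  0,   9,0.0000000000000000000,0.371190263416768862
102, 437,0.1951105648450955077,0.276487976898853904
108, 232,0.4003147563701968115,0.531880466787875150
328, 494,0.6201560624062263383,0.705187515287969857
 75, 161,0.3874805716089301244,0.545852061545647582
264, 472,0.5131710372737713355,0.604492658448094744
 34, 495,0.0487130337421188622,0.095600281030221793
 15, 225,0.0391132848152390550,0.109728071932161150
219, 361,0.5539866944003063454,0.657002494119169556
237, 252,0.9017404935283055423,0.965114949792464261
117, 329,0.3043817617949085008,0.410294360950405501
 81, 134,0.5161327972137658149,0.686740501145449267
368, 412,0.8583172887537929840,0.920533722794018461
324, 406,0.7549605812004308580,0.835336738495364273
103, 114,0.8302013406284945995,0.948475187275875098
295, 443,0.6195762917666616243,0.709326497733591799
 56, 153,0.2907872258875616178,0.448079588112874516
102, 104,0.9254937086315253580,0.996662094471866267
 90, 302,0.2476734702900827423,0.353588673952872357
180, 273,0.5993813473253911672,0.714734994259705436
 18,  58,0.1989793194564257461,0.446916201301909677
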