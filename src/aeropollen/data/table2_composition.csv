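site_id,Arecaceae,Casuarina,Urticaceae,Acacia,Myrtaceae,Chenopodiaceae,Cyperaceae,Asteraceae,Cupressaceae,Pinus,Poaceae,Plantago,Ulmus,Oleaceae,Salix,Rumex,Quercus,Alnus,Betula,Coprosma
Darwin,26.0,3.1,1.6,3.1,31.0,0.3,5.5,0.1,5.2,0.1,18.0,,,,,,,,,
Brisbane,,6.5,1.8,0.2,3.1,0.1,1.3,0.7,9.0,4.5,71.0,0.2,,,,,,,,
Perth,,,,,6.0,,,2.5,27.5,31.0,23.0,,,,,,,,,
Sydney,,6.2,0.7,0.3,11.0,,0.3,1.0,23.0,3.0,17.5,5.1,<0.1,20.0,0.2,,0.1,,,
Canberra,,1.8,1.9,0.3,5.7,0.8,1.2,0.8,22.5,17.0,15.0,3.2,3.8,1.8,1.7,4.3,3.1,3.9,1.7,
Melbourne,,0.4,0.9,0.3,5.6,0.2,,0.4,58.0,1.2,10.8,1.8,0.4,5.2,,0.1,4.9,1.8,4.5,
Hobart,,4.3,,0.5,8.2,0.3,0.5,0.5,13.3,3.3,10.4,3.4,1.6,5.2,5.0,2.3,1.6,2.0,16.7,0.4
Kaikohe,,,,,<0.1,<0.1,,0.3,0.4,0.3,84.0,11.1,,,,3.6,<0.1,,,<0.1
Auckland,,,0.1,<0.1,5.2,11.0,,2.1,1.0,0.5,43.7,16.0,,<0.1,<0.1,3.5,0.2,,0.6,0.1
Christchurch,,,,,3,6.8,0.03,2,1.7,2.4,51.6,8.6,,,0.2,6.5,11.2,,0.35,1.7
Dunedin,,,,,,,,,28.5,11.4,25.8,,,7.2,,,,,27.0,
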