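site_id,pct_water,pct_agricultural,pct_grass,pct_forest,MaxT,MinT,MAP
Darwin,45.5,0.1,0.2,54.3,33.3,19.3,1730
Brisbane,34.9,1.5,0.1,10.1,30.3,10.0,997
Perth,38.1,31.6,3.5,26.8,31.4,7.7,850
Sydney,51.1,4.2,0.3,44.3,25.9,8.0,1213
Canberra,2.2,30.2,5.1,62.5,28.0,-0.1,612
Melbourne,19.0,27.6,14.3,39.1,25.9,6.0,650
Hobart,40.2,6.3,7.3,46.2,21.6,4.5,616
Kaikohe,65.1,0.6,22.2,12.2,24.3,7.8,1304
Auckland,62.9,2.2,24.8,10.1,23.7,7.1,1239
Christchurch,57.9,20.5,18,3.6,23.0,2.0,651
Dunedin,62.4,6.1,31.1,0.4,18.9,3.2,814
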