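city,land_type,depth_2000,depth_2019
Chengdu,croplands,1,1
Chengdu,forests,1,2.75
Chengdu,grazing_lands,10.91,13.27
Chengdu,fishing_grounds,2.49,7.12
Chengdu,built_up,1,1
Deyang,croplands,1,1
Deyang,forests,1,1.18
Deyang,grazing_lands,14.63,15.88
Deyang,fishing_grounds,2.23,6.26
Deyang,built_up,1,1
Mianyang,croplands,1,1
Mianyang,forests,1,1
Mianyang,grazing_lands,1.09,1.41
Mianyang,fishing_grounds,1.78,5.34
Mianyang,built_up,1,1
Suining,croplands,1,1
Suining,forests,1,1
Suining,grazing_lands,28.39,35.86
Suining,fishing_grounds,1.32,4.11
Suining,built_up,1,1
Leshan,croplands,1,1
Leshan,forests,1,1
Leshan,grazing_lands,2.10,2.80
Leshan,fishing_grounds,1.02,5.08
Leshan,built_up,1,1
Meishan,croplands,1,1
Meishan,forests,1.04,3.87
Meishan,grazing_lands,15.84,18.74
Meishan,fishing_grounds,3.51,10.23
Meishan,built_up,1,1
Yaan,croplands,1,1
Yaan,forests,1,1
Yaan,grazing_lands,1,1
Yaan,fishing_grounds,1,1
Yaan,built_up,1,1
Ziyang,croplands,1,1
Ziyang,forests,2.80,9.06
Ziyang,grazing_lands,29.12,40.85
Ziyang,fishing_grounds,1.93,4.93
Ziyang,built_up,1,1
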