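city,ef3d_2000,ef3d_2010,ef3d_2015,ef3d_2019,change_abs,change_pct
Chengdu,4.99,6.24,4.73,4.57,-0.41,-8.32
Deyang,9.50,13.97,13.71,14.33,4.83,50.81
Mianyang,2.53,4.78,4.61,5.39,2.86,113.08
Suining,10.90,23.66,19.77,18.83,7.93,72.74
Leshan,1.84,3.29,3.65,4.18,2.33,126.56
Meishan,8.10,12.64,18.17,15.30,7.19,88.82
Yaan,1.43,2.33,2.41,2.38,0.95,66.56
Ziyang,11.02,24.10,35.19,38.76,27.74,251.77
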