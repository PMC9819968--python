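response,slice,X1,X2,X3,X4,X5,X6,X7,X8,X9,r2
ef_size,2000,10.0,6.0,4.1,11.1,4.2,10.2,9.2,20.0,25.2,0.747
ef_size,2010,12.9,10.8,10.8,6.4,10.1,7.3,9.5,14.5,17.7,0.806
ef_size,2015,8.4,17.7,16.2,14.7,11.9,10.4,5.6,5.2,9.9,0.899
ef_size,2019,11.9,12.3,15.4,12.0,10.0,7.1,12.9,3.8,14.6,0.888
ef_size,pooled,8.5,13.1,8.4,15.4,3.2,21.8,5.5,3.9,20.3,0.934
ef_depth,2000,15.2,11.7,17.8,6.8,8.1,6.4,5.0,6.5,22.5,0.728
ef_depth,2010,14.5,4.9,8.4,19.5,3.5,10.8,13.2,14.8,10.4,0.753
ef_depth,2015,11.8,8.4,4.5,8.8,8.5,6.1,40.4,7.6,3.9,0.768
ef_depth,2019,9.2,9.2,3.3,5.4,9.2,3.6,12.8,40.8,6.5,0.838
ef_depth,pooled,5.9,4.4,14.0,5.3,5.5,9.3,6.4,35.8,13.4,0.828
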