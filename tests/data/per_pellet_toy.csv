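config,reconstruction,omar,label,mean_hu,noise_hu,snr,cnr,n_pixels
unilateral,conventional,False,L1,100.0,10.0,10.0,9.0,86
unilateral,conventional,False,L2,150.0,10.0,15.0,14.0,86
unilateral,conventional,False,L3,200.0,10.0,20.0,19.0,86
unilateral,conventional,False,L4,120.0,10.0,12.0,11.0,86
unilateral,conventional,False,L5,180.0,10.0,18.0,17.0,86
unilateral,conventional,True,L1,200.0,8.0,25.0,24.0,86
unilateral,conventional,True,L2,220.0,8.0,27.5,26.5,86
unilateral,conventional,True,L3,230.0,8.0,28.75,27.75,86
unilateral,conventional,True,L4,210.0,8.0,26.25,25.25,86
unilateral,conventional,True,L5,240.0,8.0,30.0,29.0,86
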