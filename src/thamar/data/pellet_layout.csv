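side,index,x_mm,y_mm
L,1,-126.0,88.0
L,2,-132.0,98.0
L,3,-132.0,20.0
L,4,-75.0,62.0
L,5,-132.0,-60.0
L,6,-65.0,-30.0
L,7,-65.0,70.0
L,8,-60.0,-60.0
L,9,-55.0,-95.0
R,1,126.0,88.0
R,2,132.0,98.0
R,3,132.0,20.0
R,4,75.0,62.0
R,5,132.0,-60.0
R,6,65.0,-30.0
R,7,65.0,70.0
R,8,60.0,-60.0
R,9,55.0,-95.0
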