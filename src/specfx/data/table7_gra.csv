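peak,grade,rank
X4,0.849,1
X15,0.843,2
X14,0.841,3
X8,0.836,4
X6,0.835,5
X5,0.834,6
X9,0.82,7
X16,0.812,8
X12,0.794,9
X7,0.784,10
X1,0.776,11
X3,0.774,12
X2,0.772,13
X17,0.77,14
X18,0.734,15
X19,0.728,16
X11,0.685,17
X20,0.668,18
X13,0.656,19
X10,0.653,20
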