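,x1,x2,x3,y1,y2,y3
x1,1,0.711,-0.367,0.013,0.225,0.028
x2,0.711,1,-0.418,-0.477,0.259,0.238
x3,-0.367,-0.418,1,-0.055,0.173,0.327
y1,0.013,-0.477,-0.055,1,-0.255,-0.383
y2,0.225,0.259,0.173,-0.255,1,-0.058
y3,0.028,0.238,0.327,-0.383,-0.058,1
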