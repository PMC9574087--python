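specimen,position,automatic_um,manual_um
NA.550,1,162,181
NA.550,2,187,166
NA.550,3,114,128
NA.550,4,187,176
NA.550,5,162,172
NA.750,1,187,203
NA.750,2,219,237
NA.750,3,114,148
NA.750,4,187,195
NA.750,5,132,186
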