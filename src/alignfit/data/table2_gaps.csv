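specimen,region,process_temperature_C,automatic_mm3,manual_mm3
NA.550,ROI,112,24.8,25.4
NA.550,ROI,142,6.9,7.0
NA.550,ROI,173,1.7,1.0
NA.550,ROI,200,2.2,1.3
NA.750,ROI,112,16.7,16.4
NA.750,ROI,143,2.2,2.9
NA.750,ROI,176,2.0,1.7
NA.750,ROI,201,1.2,1.3
NA.750,all,176,24.6,29.4
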