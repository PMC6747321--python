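source,pollutant,unit
Indoor Monitor,PM2.5,ug/m3
Indoor Monitor,CO2,ppm
Indoor Monitor,VOC,ppb
Outdoor Monitor,PM2.5,ug/m3
Outdoor Monitor,PM10,ug/m3
Outdoor Monitor,CO,ug/m3
Outdoor Monitor,NO2,ug/m3
Outdoor Monitor,SO2,ug/m3
Outdoor Monitor,O3,ug/m3
Outdoor Monitor,NOx,ug/m3
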