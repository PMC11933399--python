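parameter,limit,unit,source,direction
Chloride,250,mg/L,WHO_EPA,above_is_hazard
Alkalinity,400,mg/L,WHO_EPA,above_is_hazard
Nitrate,10,mg/L,WHO_EPA,above_is_hazard
Nitrite,1.0,mg/L,WHO_EPA,above_is_hazard
Fluoride,1.5,mg/L,WHO_EPA,above_is_hazard
Phosphate,0.1,mg/L,WHO_EPA,above_is_hazard
TDS,600,mg/L,WHO_EPA,above_is_hazard
Hardness,500,mg/L,WHO_EPA,above_is_hazard
Iron,0.3,mg/L,WHO_EPA,below_is_hazard
Sulphate,400,mg/L,WHO_EPA,above_is_hazard
Chloride,200,mg/L,SriLanka,above_is_hazard
Alkalinity,400,mg/L,SriLanka,above_is_hazard
Nitrate,10,mg/L,SriLanka,above_is_hazard
Nitrite,0.01,mg/L,SriLanka,above_is_hazard
Fluoride,0.6,mg/L,SriLanka,above_is_hazard
Phosphate,2.0,mg/L,SriLanka,above_is_hazard
TDS,500,mg/L,SriLanka,above_is_hazard
Hardness,250,mg/L,SriLanka,above_is_hazard
Iron,1.0,mg/L,SriLanka,below_is_hazard
Sulphate,200,mg/L,SriLanka,above_is_hazard
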