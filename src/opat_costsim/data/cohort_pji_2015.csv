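case_id,age,drg_code,reason,los,actual_revenue,actual_cost,surcharge_per_diem,ward_per_diem,dischargeable_days,quarter_count,drug_daily_cost,visit_count,regimen_class
01,73,I03B,Girdlestone situation after infected hip arthroplasty,66,47539.76,40440.18,904.74,271.60,5,1,297.18,1,weekly
02,76,I12A,Early infection of hip arthroplasty,66,17594.41,23541.59,258.50,236.56,15,1,265.38,6,thrice_weekly
03,65,I12A,Late infection of knee arthroplasty,35,11116.78,20246.01,258.50,257.47,6,1,313.55,1,weekly
04,75,I04Z,Late infection of hip arthroplasty,26,11308.23,13932.11,242.34,261.47,4,1,313.55,1,weekly
05,75,I03B,Chronic late infection of hip arthroplasty,40,14754.72,23074.57,255.26,305.96,15,1,441.43,3,weekly
06,75,I12C,Chronic infection of knee arthroplasty,25,5721.10,12411.70,216.49,230.68,17,1,441.43,3,weekly
07,63,I12B,Late infection of knee arthroplasty,21,7345.24,12662.25,229.42,285.93,15,2,568.41,1,other
08,76,I01Z,Chronic late infection of hip arthroplasty,84,27495.16,45209.26,245.57,250.33,16,1,265.38,6,thrice_weekly
09,73,I03B,Girdlestone situation and osteomyelitis after infected hip arthroplasty,19,11898.53,10335.46,255.26,278.27,13,1,441.43,2,weekly
10,84,I12B,Early infection of hip arthroplasty,26,7345.24,16010.48,229.42,250.41,14,1,377.12,2,weekly
11,65,I12A,Early infection of hip arthroplasty,22,11116.78,10920.91,258.50,242.04,14,1,303.03,2,weekly
12,71,I01Z,Chronic late infection of hip arthroplasty,61,23024.62,23498.87,245.57,235.98,25,1,265.38,9,thrice_weekly
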