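record_id,age,los,flags
P001,73,66,
P002,76,66,
P003,65,35,
P004,75,26,
P005,75,40,
P006,75,25,
P007,63,21,
P008,76,84,
P009,73,19,
P010,84,26,
P011,65,22,
P012,71,61,
P013,16,14,
P014,60,1,
P015,61,2,
P016,62,3,
P017,63,4,
P018,64,5,
P019,65,6,
P020,66,1,
P021,67,2,
P022,68,3,
P023,69,4,
P024,70,5,
P025,71,6,
P026,72,1,
P027,73,2,
P028,74,3,
P029,75,4,
P030,76,5,
P031,77,6,
P032,78,1,
P033,79,2,
P034,60,3,
P035,61,4,
P036,62,5,
P037,63,6,
P038,64,1,
P039,65,2,
P040,66,3,
P041,67,4,
P042,68,5,
P043,69,6,
P044,70,1,
P045,71,2,
P046,72,3,
P047,55,10,complex_case
P048,56,11,complex_case
P049,57,12,complex_case
P050,58,13,complex_case
P051,59,14,complex_case
P052,60,15,complex_case
P053,61,16,complex_case
P054,62,17,complex_case
P055,63,18,complex_case
P056,64,19,complex_case
P057,65,20,complex_case
P058,66,21,complex_case
P059,67,22,complex_case
P060,68,23,complex_case
P061,69,24,complex_case
P062,70,25,complex_case
P063,71,26,complex_case
P064,72,27,complex_case
P065,73,28,complex_case
P066,74,29,complex_case
P067,75,30,complex_case
P068,76,31,complex_case
P069,77,32,complex_case
P070,78,33,complex_case
P071,79,34,complex_case
P072,55,35,complex_case
P073,56,36,complex_case
P074,57,37,complex_case
P075,58,38,complex_case
P076,50,9,non_hip_knee_implant
P077,51,10,non_hip_knee_implant
P078,52,11,non_hip_knee_implant
P079,53,12,non_hip_knee_implant
P080,54,13,non_hip_knee_implant
P081,55,14,non_hip_knee_implant
P082,56,15,non_hip_knee_implant
P083,57,16,non_hip_knee_implant
P084,58,17,non_hip_knee_implant
P085,59,18,non_hip_knee_implant
P086,60,19,non_hip_knee_implant
P087,61,20,non_hip_knee_implant
P088,62,21,non_hip_knee_implant
P089,63,22,non_hip_knee_implant
P090,64,23,non_hip_knee_implant
P091,65,24,non_hip_knee_implant
P092,66,25,non_hip_knee_implant
P093,67,26,non_hip_knee_implant
P094,68,27,non_hip_knee_implant
P095,69,28,non_hip_knee_implant
P096,70,29,non_hip_knee_implant
P097,71,30,non_hip_knee_implant
P098,72,31,non_hip_knee_implant
P099,73,32,non_hip_knee_implant
P100,74,33,non_hip_knee_implant
P101,75,9,non_hip_knee_implant
P102,58,8,no_antibiotics
P103,59,9,no_antibiotics
P104,60,10,no_antibiotics
P105,61,11,no_antibiotics
P106,62,12,no_antibiotics
P107,63,13,no_antibiotics
P108,64,14,no_antibiotics
P109,65,15,no_antibiotics
P110,66,16,no_antibiotics
P111,67,17,no_antibiotics
P112,68,18,no_antibiotics
P113,69,19,no_antibiotics
P114,70,20,no_antibiotics
P115,71,21,no_antibiotics
P116,72,22,no_antibiotics
P117,62,12,no_infection
P118,63,13,no_infection
P119,64,14,no_infection
P120,65,15,no_infection
P121,66,16,no_infection
P122,66,15,oral_antibiotics
P123,67,16,oral_antibiotics
P124,68,17,oral_antibiotics
P125,69,18,oral_antibiotics
P126,59,7,transferred
P127,60,8,transferred
P128,61,9,transferred
P129,62,10,transferred
P130,63,11,transferred
P131,64,12,transferred
P132,65,13,transferred
P133,66,14,transferred
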