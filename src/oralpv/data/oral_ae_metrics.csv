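term,group,n_pei,arr_pei,n_vaers,arr_vaers,prr,prr_low,prr_high,ror,ror_low,ror_high,ic,ic025,sdr,or,or_low,or_high
taste disorder,taste,481,0.493,296,0.291,17.57,10.28,30.03,17.57,10.28,30.04,4.14,3.60,yes,1.69,1.47,1.96
ageusia,taste,438,0.449,3491,3.436,15.51,13.39,17.97,15.56,13.43,18.03,3.96,3.81,yes,0.13,0.12,0.14
oral herpes,oral_mucosa,401,0.411,433,0.426,1.36,1.17,1.59,1.36,1.17,1.59,0.45,0.29,no,0.97,0.84,1.11
dysgeusia,taste,352,0.361,2232,2.197,3.31,3.02,3.63,3.32,3.02,3.64,1.73,1.64,yes,0.16,0.15,0.18
paraesthesia oral,sensation,317,0.325,1183,1.164,4.47,3.87,5.16,4.47,3.87,5.16,2.16,2.02,yes,0.28,0.25,0.32
hypoaesthesia oral,sensation,311,0.319,1132,1.114,4.26,3.69,4.92,4.26,3.69,4.92,2.09,1.95,yes,0.29,0.25,0.32
swollen tongue,tongue,290,0.297,584,0.575,2.70,2.28,3.19,2.70,2.28,3.19,1.43,1.26,yes,0.52,0.45,0.60
dry mouth,salivary_glands,270,0.277,626,0.616,2.59,2.21,3.03,2.59,2.21,3.04,1.37,1.21,yes,0.45,0.39,0.52
lip swelling,lips,252,0.258,1721,1.694,1.54,1.42,1.67,1.54,1.42,1.67,0.62,0.54,no,0.15,0.13,0.17
aphthous ulcer,oral_mucosa,126,0.129,275,0.271,4.48,3.32,6.04,4.48,3.32,6.04,2.16,1.87,yes,0.48,0.39,0.59
oral disorder,oral_mucosa,119,0.122,44,0.043,1.74,1.04,2.93,1.74,1.04,2.93,0.80,0.28,no,2.82,1.99,3.98
tongue disorder,tongue,111,0.114,72,0.071,1.62,1.09,2.40,1.62,1.09,2.40,0.69,0.30,no,1.61,1.19,2.16
stomatitis,oral_mucosa,88,0.09,120,0.118,0.66,0.52,0.83,0.66,0.52,0.83,-0.61,-0.85,no,0.76,0.58,1.01
hypogeusia,taste,82,0.084,30,0.03,3.56,1.56,8.11,3.56,1.56,8.11,1.83,1.01,yes,2.85,1.88,4.33
mouth swelling,oral_mucosa,52,0.053,133,0.131,2.35,1.69,3.28,2.35,1.69,3.28,1.23,0.90,yes,0.41,0.30,0.56
hyper salivation,salivary_glands,35,0.036,0,0,,,,,,,,,disqualified,inf,,
glossodynia,tongue,31,0.032,177,0.174,2.49,1.86,3.35,2.49,1.86,3.35,1.32,1.02,yes,0.18,0.12,0.27
oral mucosal erythema,oral_mucosa,25,0.026,8,0.008,1.33,0.44,4.06,1.33,0.44,4.06,0.41,-0.71,no,3.26,1.47,7.22
sialadenitis,salivary_glands,22,0.023,0,0,,,,,,,,,disqualified,inf,,
tongue coated,tongue,20,0.021,2,0.002,,,,,,,,,disqualified,10.42,2.44,44.59
lip oedema,lips,19,0.019,22,0.022,1.52,0.75,3.08,1.52,0.75,3.08,0.61,-0.10,no,0.90,0.49,1.66
tongue paralysis,tongue,15,0.015,2,0.002,0.33,0.06,1.71,0.33,0.06,1.71,-1.59,-3.23,no,7.82,1.79,34.18
anaesthesia oral,sensation,15,0.015,10,0.01,8.31,1.06,64.91,8.31,1.06,64.91,3.06,1.00,yes,1.56,0.70,3.48
oral mucosal blister,oral_mucosa,15,0.015,63,0.062,1.03,0.71,1.49,1.03,0.71,1.49,0.04,-0.33,no,0.25,0.14,0.44
dental discomfort,dentition,15,0.015,32,0.031,,,,,,,,,disqualified,0.49,0.26,0.90
oral dysaesthesia,sensation,14,0.014,1,0.001,,,,,,,,,disqualified,14.59,1.92,110.96
cheilitis,lips,14,0.014,201,0.198,1.51,1.19,1.90,1.51,1.19,1.90,0.59,0.36,no,0.07,0.04,0.12
noninfective sialoadenitis,salivary_glands,13,0.013,5,0.005,,,,,,,,,disqualified,2.71,0.97,7.60
tongue movement disturbance,tongue,13,0.013,6,0.006,4.99,0.60,41.41,4.99,0.60,41.41,2.32,0.20,no,2.26,0.86,5.94
oral candidiasis,oral_mucosa,13,0.013,33,0.032,1.83,0.99,3.37,1.83,0.99,3.37,0.87,0.26,no,0.41,0.22,0.78
lip dry,lips,13,0.013,33,0.032,2.29,1.18,4.42,2.29,1.18,4.42,1.19,0.53,yes,0.41,0.22,0.78
glossitis,tongue,12,0.012,49,0.048,1.40,0.89,2.22,1.40,0.89,2.22,0.49,0.03,no,0.26,0.14,0.48
trichoglossia,tongue,10,0.01,1,0.001,,,,,,,,,disqualified,10.42,1.33,81.41
palatal swelling,palate,10,0.01,13,0.013,,,,,,,,,disqualified,0.80,0.35,1.83
aptyalism,salivary_glands,9,0.009,15,0.015,6.23,1.43,27.25,6.23,1.43,27.25,2.64,1.16,yes,0.63,0.27,1.43
tongue blistering,tongue,9,0.009,19,0.019,3.16,1.18,8.46,3.16,1.18,8.46,1.66,0.67,yes,0.49,0.22,1.09
tongue eruption,tongue,9,0.009,6,0.006,2.49,0.50,12.35,2.49,0.50,12.35,1.32,-0.28,no,1.56,0.56,4.39
tongue oedema,tongue,9,0.009,3,0.003,0.05,0.02,0.17,0.05,0.02,0.17,-4.24,-5.40,no,3.13,0.85,11.55
oral mucosa erosion,oral_mucosa,9,0.009,1,0.001,,,,,,,,,disqualified,9.38,1.19,74.04
oral pruritus,oral_mucosa,9,0.009,112,0.11,2.39,1.66,3.44,2.39,1.66,3.44,1.26,0.89,yes,0.08,0.04,0.17
perioral dermatitis,oral_mucosa,9,0.009,1,0.001,0.83,0.05,13.29,0.83,0.05,13.29,-0.27,-3.04,no,9.38,1.19,74.04
hyperaesthesia teeth,dentition,9,0.009,44,0.043,9.14,3.28,25.44,9.14,3.28,25.44,3.19,2.17,yes,0.21,0.10,0.44
tongue discolouration,tongue,8,0.008,27,0.027,1.40,0.76,2.60,1.40,0.76,2.60,0.49,-0.13,no,0.31,0.14,0.68
oral lichen planus,oral_mucosa,8,0.008,8,0.008,3.32,0.71,15.65,3.32,0.71,15.65,1.73,0.18,no,1.04,0.39,2.78
oral fungal infection,oral_mucosa,7,0.007,4,0.004,3.32,0.37,29.74,3.32,0.37,29.74,1.73,-0.46,no,1.82,0.53,6.23
oral mucosal eruption,oral_mucosa,7,0.007,52,0.051,1.49,0.95,2.35,1.49,0.95,2.35,0.58,0.12,no,0.14,0.06,0.31
salivary gland enlargement,salivary_glands,6,0.006,11,0.011,1.31,0.51,3.37,1.31,0.51,3.37,0.39,-0.56,no,0.57,0.21,1.54
saliva changes,salivary_glands,6,0.006,0,0,,,,,,,,,disqualified,inf,,
angular cheilitis,lips,6,0.006,11,0.011,2.29,0.73,7.18,2.29,0.73,7.18,1.19,0.05,no,0.57,0.21,1.54
lip blister,lips,6,0.006,74,0.073,1.28,0.89,1.84,1.28,0.89,1.84,0.36,-0.01,no,0.08,0.04,0.19
circumoral swelling,oral_mucosa,5,0.005,31,0.031,3.68,1.62,8.36,3.68,1.62,8.36,1.88,1.06,yes,0.17,0.07,0.43
tongue dry,tongue,4,0.004,11,0.011,,,,,,,,,disqualified,0.38,0.12,1.19
tongue erythema,tongue,4,0.004,13,0.013,3.60,1.03,12.64,3.60,1.03,12.64,1.85,0.59,yes,0.32,0.10,0.98
tongue ulceration,palate,4,0.004,18,0.018,1.25,0.60,2.59,1.25,0.60,2.59,0.32,-0.41,no,0.23,0.08,0.68
palatal disorder,palate,4,0.004,3,0.003,2.49,0.26,23.97,2.49,0.26,23.97,1.32,-0.95,no,1.39,0.31,6.21
lip disorder,lips,4,0.004,33,0.032,3.92,1.73,8.86,3.92,1.73,8.86,1.97,1.15,yes,0.13,0.04,0.36
lip erythema,lips,4,0.004,28,0.028,2.59,1.22,5.48,2.59,1.22,5.48,1.37,0.62,yes,0.15,0.05,0.42
lip pain,lips,4,0.004,59,0.058,1.96,1.23,3.13,1.96,1.23,3.13,0.97,0.50,no,0.07,0.03,0.19
chapped lips,lips,3,0.003,128,0.126,2.53,1.79,3.59,2.53,1.79,3.59,1.34,0.99,yes,0.02,0.01,0.08
dental paraesthesia,dentition,3,0.003,12,0.012,9.97,1.30,76.69,9.97,1.30,76.69,3.32,1.28,yes,0.26,0.07,0.92
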