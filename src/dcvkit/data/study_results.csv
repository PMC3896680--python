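item_id,intended,mean,t,sig_intended,coallocated,sig_other
Q01,D1,0.82,9.99,1,,
Q02,D1,0.88,17.58,1,,
Q03,D1,0.82,8.76,1,,
Q04,D1,0.74,5.51,1,,
Q05,D1,0.20,1.03,0,D2;D4;D14,
Q06,D1,0.44,2.63,0,D2,
Q07,D2,0.86,16.42,1,,
Q08,D2,-0.01,-0.05,0,D4,
Q09,D2,0.53,3.84,1,,
Q10,D2,0.67,5.28,1,,
Q11,D3,0.85,9.62,1,,
Q12,D3,0.89,29.74,1,,
Q13,D3,0.82,7.90,1,,
Q14,D3,0.81,8.70,1,,
Q15,D4,0.71,5.80,1,,
Q16,D4,0.67,5.31,1,,
Q17,D4,0.78,7.07,1,,
Q18,D4,0.02,0.11,0,D2;D14,
Q19,D4,0.40,2.17,0,D2;D5,
Q20,D4,0.33,2.21,0,D2;D5;D6,
Q21,D5,0.64,5.01,1,,
Q22,D5,0.65,4.35,1,,
Q23,D5,0.13,0.65,0,D6,
Q24,D5,0.43,3.13,0,D4;D6,
Q25,D5,0.03,0.14,0,D4;D6,
Q26,D5,0.44,2.60,0,D6,
Q27,D6,0.45,2.71,0,D5,
Q28,D6,0.42,2.82,0,D1;D3,
Q29,D6,0.60,4.44,1,,
Q30,D6,0.58,4.14,1,,
Q31,D7,0.42,2.38,0,D6,
Q32,D7,-0.51,-3.77,0,D3;D6;D12,D12
Q33,D7,-0.68,-7.14,0,D4;D6;D13,D6
Q34,D8,0.73,6.92,1,,
Q35,D8,0.63,3.89,1,,
Q36,D8,0.66,5.83,1,,
Q37,D8,0.89,20.60,1,,
Q38,D9;D14,0.47,2.75,0,D8,
Q39,D9;D14,0.26,1.22,0,D8,
Q40,D9;D14,0.43,2.26,0,D8,
Q41,D9;D14,-0.18,-0.83,0,D8,
Q42,D9,-0.58,-4.10,0,D3;D10;D11,D10
Q43,D9,-0.58,-4.30,0,D3;D10;D11,D10
Q44,D9,-0.49,-4.32,0,D3;D10;D11;D14,D10;D11
Q45,D9,-0.63,-4.82,0,D3;D10;D11,D10
Q46,D10,0.32,1.64,0,D1;D4,
Q47,D10,0.63,4.55,1,,
Q48,D10,-0.66,-5.52,0,D1;D4,D4
Q49,D10,-0.91,-30.09,0,D1,D1
Q50,D10,0.77,7.10,1,,
Q51,D10,0.52,3.24,0,,
Q52,D10,0.68,5.06,1,,
Q53,D10,0.68,6.03,1,,
Q54,D11,0.22,1.44,0,D1;D3,
Q55,D11,0.25,1.55,0,D3;D6;D12,
Q56,D11,-0.02,-0.11,0,D2;D3;D12;D14,
Q57,D11,0.42,2.24,0,D3,
Q58,D11,0.86,13.48,1,,
Q59,D11,0.74,9.35,1,,
Q60,D11,-0.51,-3.29,0,D2,
Q61,D11,0.13,0.69,0,D7,
Q62,D12,-0.35,-1.96,0,D3;D11,
Q63,D12,0.22,1.30,0,D3;D11,
Q64,D12,0.14,0.74,0,D11,
Q65,D12,0.07,0.38,0,D3;D11,
Q66,D12,0.84,9.04,1,,
Q67,D12,0.61,3.97,1,,
Q68,D12,0.35,2.13,0,D3;D11,
Q69,D12,0.24,1.26,0,D3;D11,
Q70,D13,-0.09,-0.49,0,D3;D14,
Q71,D13,-0.01,-0.05,0,D3;D4,
Q72,D13,0.55,3.55,1,,
Q73,D13,0.78,6.95,1,,
Q74,D14,-0.31,-0.20,0,D2;D10,
Q75,D14,-0.45,-3.29,0,D2;D10,
Q76,D14,0.27,1.57,0,D7;D9;D13,
Q77,D14,-0.39,-2.53,0,D9,
Q78,D14,-0.09,-0.49,0,D8;D9;D10,
Q79,D14,0.49,3.45,0,D9,
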