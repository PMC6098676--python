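year,pfc,f_calf,f_subadult,f_adult,m_calf,m_subadult,m_adult,f_calf_imports,f_subadult_imports,f_adult_imports,m_calf_imports,m_subadult_imports,m_adult_imports,f_calf_exports,f_subadult_exports,f_adult_exports,m_calf_exports,m_subadult_exports,m_adult_exports
1986,,0,1,1,0,0,1,0,1,1,0,0,1,0,0,0,0,0,0
1987,0,0,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
1988,1,1,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
1989,0,1,3,1,0,1,1,0,2,0,0,1,0,0,0,0,0,0,0
1990,0.3333,2,2,3,0,2,1,0,0,1,0,1,0,0,0,0,0,0,0
1991,0.5,2,1,4,1,2,1,0,0,0,0,0,0,0,0,0,0,0,0
1992,0.5,3,2,4,2,2,1,0,1,0,0,0,1,0,0,0,0,0,0
1993,0.25,2,4,4,2,0,3,0,0,0,0,0,0,0,0,0,0,0,0
1994,0.8,4,4,5,1,2,3,0,0,0,0,0,0,0,0,0,0,0,0
1995,0.3333,3,4,6,3,2,3,0,0,0,0,0,0,0,0,0,0,0,0
1996,0.125,3,2,8,4,2,3,0,0,0,0,0,0,0,0,0,0,0,0
1997,0.5,4,12,8,2,9,4,0,7,0,0,5,1,0,0,0,0,0,0
1998,0.4444,5,11,8,3,11,4,0,0,0,0,0,0,0,0,0,0,0,0
1999,0.4444,6,13,9,3,10,5,0,0,0,0,0,0,0,0,0,0,0,0
2000,0.0833,7,9,12,3,9,6,0,0,0,0,0,0,0,0,0,0,0,0
2001,0.6471,6,9,17,7,12,6,0,0,0,0,0,0,0,0,0,0,0,0
2002,0.1667,7,9,18,7,8,10,0,0,0,0,0,0,0,0,0,0,0,0
2003,0.6,12,10,20,7,7,14,0,0,0,0,0,0,0,0,0,0,0,0
2004,0.3478,13,11,23,7,8,15,0,0,0,0,0,0,0,0,0,0,0,0
2005,0.4,12,13,24,10,10,15,0,0,0,0,0,0,0,0,0,0,0,0
2006,0.5556,12,14,27,14,9,17,0,0,0,0,0,0,0,4,0,0,1,0
2007,0.2593,11,16,27,15,13,16,0,0,0,0,0,0,0,0,0,0,0,0
2008,0.4483,14,19,29,13,19,16,0,0,0,0,0,0,0,0,0,0,0,0
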