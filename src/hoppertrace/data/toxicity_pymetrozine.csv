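site_id,region,insecticide,lc50_mg_L,ci_lower,ci_upper,slope,slope_se,chi2,letter
Hongjiang,HN,pymetrozine,29.208,26.377,32.467,3.090,0.304,0.388,a
Linli,HN,pymetrozine,28.659,26.026,31.459,3.462,0.318,0.913,a
Longshan,HN,pymetrozine,32.067,28.960,35.801,3.092,0.306,0.067,a
Hanshou,HN,pymetrozine,27.042,24.511,29.677,3.471,0.322,1.554,a
Zhijiang,HN,pymetrozine,27.009,24.437,29.685,3.401,0.319,0.587,a
Dongan,HN,pymetrozine,43.545,39.446,48.026,3.386,0.313,4.131,b
Shuangfeng,HN,pymetrozine,41.903,37.682,46.424,3.073,0.302,0.588,b
Ningxiang,HN,pymetrozine,43.690,39.669,48.100,3.404,0.314,2.999,b
Linxiang,HN,pymetrozine,42.511,38.605,46.741,3.701,0.326,2.887,b
Xiangyin,HN,pymetrozine,40.737,36.703,45.029,3.157,0.306,0.937,b
Qidong,HN,pymetrozine,41.588,37.071,46.449,2.805,0.293,0.352,b
Daoxian,HN,pymetrozine,55.945,53.516,58.417,7.407,0.696,1.071,c
Youxian,HN,pymetrozine,56.131,53.789,58.522,7.764,0.711,0.945,c
Guiyang,HN,pymetrozine,54.250,52.106,56.389,8.567,0.755,2.569,c
Yizhang,HN,pymetrozine,53.910,51.502,56.283,7.427,0.698,0.218,c
Quanzhou,GX,pymetrozine,18.512,16.894,20.305,3.572,0.322,0.934,d
Yongfu,GX,pymetrozine,21.341,19.513,23.373,3.667,0.325,1.273,d
Longzhou,GX,pymetrozine,28.091,25.568,30.751,3.600,0.323,1.740,a
Jinchengjiang,GX,pymetrozine,31.235,28.777,33.907,4.167,0.351,1.003,a
Liujiang,GX,pymetrozine,42.548,38.525,46.867,3.308,0.310,1.041,b
Xingbin,GX,pymetrozine,43.401,39.246,47.924,3.221,0.308,0.098,b
Fangchenggang,GX,pymetrozine,47.518,41.579,54.253,2.470,0.221,1.194,bc
Hepu,GX,pymetrozine,47.063,40.847,54.143,2.297,0.214,0.389,bc
Bobai,GX,pymetrozine,46.959,40.446,54.429,2.331,0.216,0.224,bc
Zhaoping,GX,pymetrozine,58.090,55.517,60.802,7.051,0.676,1.325,c
Babu,GX,pymetrozine,57.292,54.863,59.817,7.502,0.697,0.772,c
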