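site_id,region,insecticide,lc50_mg_L,ci_lower,ci_upper,slope,slope_se,chi2,letter
Hongjiang,HN,nitenpyram,0.906,0.729,1.096,3.090,0.304,0.388,a
Linli,HN,nitenpyram,1.002,0.922,1.087,3.462,0.318,0.913,a
Longshan,HN,nitenpyram,0.922,0.851,0.996,3.092,0.306,0.067,a
Hanshou,HN,nitenpyram,0.975,0.887,1.067,3.471,0.322,1.554,a
Zhijiang,HN,nitenpyram,1.083,0.991,1.181,3.401,0.319,0.587,a
Dongan,HN,nitenpyram,2.622,2.379,2.886,3.386,0.313,4.131,b
Shuangfeng,HN,nitenpyram,2.614,2.389,2.858,3.073,0.302,0.588,b
Ningxiang,HN,nitenpyram,2.815,2.598,3.056,3.404,0.314,2.999,b
Linxiang,HN,nitenpyram,2.602,2.393,2.828,3.701,0.326,2.887,b
Xiangyin,HN,nitenpyram,2.767,2.546,3.007,3.157,0.306,0.937,b
Qidong,HN,nitenpyram,2.392,1.948,2.897,2.805,0.293,0.352,b
Daoxian,HN,nitenpyram,3.899,3.566,4.249,7.407,0.696,1.071,c
Youxian,HN,nitenpyram,3.536,3.236,3.842,7.764,0.711,0.945,c
Guiyang,HN,nitenpyram,4.209,3.834,4.613,8.567,0.755,2.569,c
Yizhang,HN,nitenpyram,4.071,3.721,4.443,7.427,0.698,0.218,c
Quanzhou,GX,nitenpyram,0.648,0.591,0.709,3.572,0.322,0.934,d
Yongfu,GX,nitenpyram,0.649,0.597,0.705,3.667,0.325,1.273,d
Longzhou,GX,nitenpyram,1.100,0.983,1.218,3.600,0.323,1.740,a
Jinchengjiang,GX,nitenpyram,1.105,0.988,1.225,4.167,0.351,1.003,a
Liujiang,GX,nitenpyram,2.623,2.382,2.872,3.308,0.310,1.041,b
Xingbin,GX,nitenpyram,2.853,2.318,3.476,3.221,0.308,0.098,b
Fangchenggang,GX,nitenpyram,3.297,2.679,4.061,2.470,0.221,1.194,bc
Hepu,GX,nitenpyram,3.316,2.804,3.909,2.297,0.214,0.389,bc
Bobai,GX,nitenpyram,3.260,2.751,3.847,2.331,0.216,0.224,bc
Zhaoping,GX,nitenpyram,4.140,3.778,4.526,7.051,0.676,1.325,c
Babu,GX,nitenpyram,3.726,3.376,4.086,7.502,0.697,0.772,c
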