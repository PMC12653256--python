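site_id,region,lat,lon
Linxiang,HN,29.34,113.42
Xiangyin,HN,28.71,112.80
Ningxiang,HN,28.15,112.35
Linli,HN,29.49,111.61
Longshan,HN,29.22,109.50
Hanshou,HN,28.84,111.71
Hongjiang,HN,27.25,110.09
Qidong,HN,26.80,111.95
Zhijiang,HN,27.40,109.60
Dongan,HN,26.49,111.32
Daoxian,HN,25.50,111.59
Shuangfeng,HN,27.46,112.17
Guiyang,HN,25.59,112.59
Yizhang,HN,25.27,112.92
Youxian,HN,27.17,113.48
Fangchenggang,GX,22.01,108.35
Hepu,GX,21.94,109.34
Bobai,GX,22.22,109.87
Liujiang,GX,24.02,109.34
Xingbin,GX,23.46,109.28
Longzhou,GX,22.42,107.35
Zhaoping,GX,24.10,111.96
Babu,GX,24.42,111.55
Jinchengjiang,GX,24.70,108.06
Yongfu,GX,24.99,109.98
Quanzhou,GX,25.93,111.01
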