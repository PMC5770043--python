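semester,complied,zone,n,n_ipsi
1,0,green,30,0
1,0,red,162,0
1,0,yellow,135,0
1,1,green,91,0
1,1,red,330,105
1,1,excluded,1,0
1,1,yellow,322,16
2,0,green,21,0
2,0,red,104,0
2,0,yellow,80,0
2,1,green,81,0
2,1,red,250,46
2,1,yellow,239,12
3,0,green,20,0
3,0,red,92,0
3,0,excluded,2,0
3,0,yellow,72,0
3,1,green,82,0
3,1,red,210,64
3,1,yellow,207,15
4,0,green,10,0
4,0,red,23,0
4,0,excluded,1,0
4,0,yellow,25,0
4,1,green,15,0
4,1,red,78,46
4,1,yellow,48,7
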