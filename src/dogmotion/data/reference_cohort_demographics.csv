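subject_id,group,sex,age,weight,neutered
Wally,C,m,3,23,y
Gino,C,m,0.67,44,n
Jema,C,f,3,25,y
Laila,C,f,1,20,y
Loli,C,f,6,17,y
Misty,C,f,2.5,20,y
Pie,C,m,1,25,y
Sparki,C,m,5,40,n
Mila,C,f,3.5,22,y
Mika,C,f,7,7,y
Theresa,C,f,0.67,16.5,y
Pit,C,m,1,25,y
Sia,H,f,2,19,y
Tomy,H,m,2.5,13,y
Humus,H,m,1.5,23,y
Indi,H,f,1.5,20,y
Max,H,m,1,36,y
Pit_H,H,m,3,24,y
Nancy,H,m,0.67,21,y
Bana,H,f,1.5,32,y
Patrick,H,m,0.5,23,n
Mitch,H,m,6,13,n
Lichi,H,f,7,22,y
Kim,H,f,1,18,y
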