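chemical,reference_class,ar2_agonist,ot_8h,ot_16h,upitt_agonist
17beta-Trenbolone,strong,1,1,1,NT
17-Methyltestosterone,strong,1,1,1,0
Levonorgestrel,strong,1,1,1,0
Norethindrone,strong,1,1,1,0
Testosterone propionate,strong,1,1,1,0
"4-Androstene-3,17-dione",moderate,1,1,1,0
5alpha-Dihydrotestosterone,moderate,1,1,1,0
Cyproterone acetate,weak,1,1,1,1
17alpha-Estradiol,inactive,1,1,1,1
Atrazine,inactive,0,0,0,0
Benomyl,inactive,0,0,1,0
Carbendazim,inactive,0,0,1,0
Cyfluthrin,inactive,0,0,0,0
Cypermethrin,inactive,0,0,0,0
Deltamethrin,inactive,0,0,0,0
Fenarimol,inactive,0,0,1,1
Finasteride,inactive,0,0,0,1
Flutamide,inactive,0,1,1,1
Fulvestrant,inactive,0,0,0,0
"o,p'-DDT",inactive,0,1,1,1
Permethrin,inactive,0,0,0,0
Prochloraz,inactive,1,1,1,1
Tamoxifen,inactive,0,1,1,1
Tetramethrin,inactive,0,1,1,0
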