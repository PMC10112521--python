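chemical,reference_class,ar2_antagonist,ot_8h,ot_16h,upitt_antagonist
Bicalutamide,strong,1,1,1,1
Fenitrothion,strong,1,1,1,1
Hydroxyflutamide,strong,0,1,1,NT
Mifepristone,strong,1,1,1,1
Spironolactone,strong,1,1,1,0
Bisphenol A,moderate,1,0,1,1
Cyproterone acetate,moderate,0,1,1,1
Flutamide,moderate,1,1,1,1
Linuron,moderate,1,0,0,1
Prochloraz,moderate,1,1,1,1
Fenarimol,weak,1,0,1,1
Methoxychlor,weak,1,0,1,1
"o,p'-DDT",weak,1,1,1,1
Procymidone,weak,1,0,0,1
Propiconazole,weak,1,1,1,1
Vinclozolin,weak,1,1,1,1
Zearalenone,weak,1,0,0,1
17-Methyltestosterone,inactive,1,1,1,0
"4-Androstene-3,17-dione",inactive,1,1,1,0
Atrazine,inactive,0,0,0,0
Deltamethrin,inactive,0,0,0,0
Methomyl,inactive,0,0,0,0
Simazine,inactive,0,0,0,0
Testosterone propionate,inactive,1,1,1,0
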