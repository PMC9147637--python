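chemical,cas,dpra_call,invivo_call,invivo_assay,ec3,ke2_call,ke3_call,easa_call
"1,2-Propanediol",57-55-6,Nonbinder,Nonsensitizer,LLNA,,,,Binder
12-Bromo-1-dodecanol,3344-77-2,,Sensitizer,LLNA,6.9,,,Nonbinder
1-Butanol,71-36-3,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
1-Butyl-1-methylpyrrolidinium chloride,479500-35-1,,,,,,,Nonbinder
1-Butyl-3-methylimidazolium chloride,79917-90-1,,,,,,,Nonbinder
1-Ethyl-3-methylimidazolium chloride,65039-09-0,,,,,,,Nonbinder
1-Hydroxy-4-(p-toluidino) anthraquinone,81-48-1,,,,,,,Binder
"2,3-Butanedione",431-03-8,Binder,Sensitizer,LLNA,11,,,Binder
"2,4,5-Trichlorophenoxyacetic acid",93-76-5,,Sensitizer,LLNA,9.87,,,Nonbinder
"2,4-Diaminotoluene",95-80-7,,Sensitizer,LLNA,19,,,Binder
"2,4-Dichloronitrobenzene",611-06-3,,Sensitizer,LLNA,,,,Binder
2-Amino-6-chloro-4-nitrophenol,6358-09-4,,Sensitizer,LLNA,2.2,,,Binder
2-Mercaptobenzothiazole,149-30-4,Binder,Sensitizer,LLNA,1.7,,,Binder
2-Methoxy-4-nitroaniline,97-52-9,,Nonsensitizer,GPMT,,,,Binder
"2-Methyl-4H,3,1-benzoxazin-4-one (Product 2040)",525-76-8,,Sensitizer,LLNA,0.7,,,Inconclusive
"3,4-Dihydrocoumarin",119-84-6,Binder,Sensitizer,LLNA,5.6,,,Binder
3-Iodo-2-propynyl butylcarbamate,55406-53-6,Binder,Sensitizer,LLNA,0.9,,,Binder
4-Chloro-o-phenylenediamine,95-83-0,,,,,,,Binder
4'-Hydroxychalcone,2657-25-2,,Sensitizer,LLNA,0.002,,,Binder
4-Methylcyclohexanemethanol,34885-03-5,,,,,,,Nonbinder
4-Phenylenediamine,106-50-3,Binder,Sensitizer,LLNA,0.16,,,Binder
5-Amino-o-cresol,2835-95-2,Binder,Sensitizer,LLNA,3.4,,,Binder
Ammonium thiosulfate,7783-18-8,,Nonsensitizer,LLNA,,,,Nonbinder
Aniline,62-53-3,Nonbinder,Sensitizer,LLNA,0.9,,,Binder
Annatto,1393-63-1,,Sensitizer,LLNA,5,,,Binder
Atrazine,1912-24-9,,Sensitizer,LLNA,31.3 to 41.4,,,Nonbinder
Azithromycin,83905-01-5,,,,,,,Binder
Benzalkonium chloride,8001-54-5,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
Benzethonium chloride,121-54-0,,,,,,,Nonbinder
Benzyl benzoate,120-51-4,Nonbinder,Sensitizer,LLNA,17,,,Nonbinder
Benzyl bromide,100-39-0,Binder,Sensitizer,LLNA,0.2,,,Binder
Benzyl salicylate,118-58-1,Nonbinder,Sensitizer,LLNA,2.9,,,Binder
Camphorquinone,10373-78-1,,Sensitizer,LLNA,10,,,Binder
Chlorpyrifos,2921-88-2,,Sensitizer,LLNA,6.91,,,Binder
Cinnamic aldehyde,104-55-2,Binder,Sensitizer,LLNA,3.1,,,Binder
Cinnamyl Alcohol,104-54-1,Binder,Sensitizer,LLNA,21,,,Binder
cis-Bixin,6983-79-5,,Sensitizer,LLNA,0.1,,,Binder
Citral,5392-40-5,Binder,Sensitizer,LLNA,4.6 to 13,,,Binder
Clarithromycin,81103-11-9,,,,,,,Binder
D-glucose,50-99-7,Binder,Nonsensitizer,LLNA,,,,Nonbinder
Dicyclohexylcarbodiimide,538-75-0,,,,,,,Binder
Diethyl maleate,141-05-9,Binder,Sensitizer,LLNA,2.1,,,Nonbinder
Dinitrochlorobenzene,97-00-7,Binder,Sensitizer,LLNA,0.04,,,Binder
Ethyl vanillin,121-32-4,Nonbinder,Nonsensitizer,LLNA,,,,Binder
Ethylene thiourea,96-45-7,,,,,,,Nonbinder
Fluconazole,86386-73-4,,,,,,,Binder
Formaldehyde,50-00-0,Binder,Sensitizer,LLNA,0.61,,,Binder
Furil,492-94-4,Binder,Nonsensitizer,LLNA,,,,Binder
Glutaraldehyde,111-30-8,Binder,Sensitizer,LLNA,0.1,,,Binder
Glycerol,56-81-5,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
Glyoxal,107-22-2,Binder,Sensitizer,LLNA,1.4,,,Binder
Heptachlor (solution),76-44-8,,,,,,,Nonbinder
Iso-E Super,54464-57-2,,Sensitizer,LLNA,,,,Binder
Isophorone diisocyanate,4098-71-9,Binder,Sensitizer,LLNA,0.1,,,Binder
Isopropanol,67-63-0,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
Methyl pyruvate,600-22-6,Nonbinder,Sensitizer,LLNA,2.4,,,Binder
Methyl salicylate,119-36-8,Nonbinder,Sensitizer,LLNA,,,,Binder
"N,N-Diethyl-m-aminophenol",91-68-9,,Sensitizer,LLNA,,,,Binder
"N,N-Dimethylformamide",68-12-2,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
o-Benzyl-p-chlorophenol,120-32-1,,,,,,,Binder
o-Cresol,95-48-7,,,,,,,Binder
"p,p'-Biphenol",92-88-6,,,,,,,Inconclusive
Palladium di(4-oxapent-2-en-2-oate),14024-61-4,,,,,,,Binder
Penicillin,61-33-6,Binder,Sensitizer,LLNA,30,,,Nonbinder
Pentaerythritol triacrylate,3524-68-3,,,,,,,Binder
Perillaldehyde,2111-75-3,Binder,Sensitizer,LLNA,8.1,,,Binder
Phenylacetaldehyde,122-78-1,Binder,Sensitizer,LLNA,3 to 4.7,,,Binder
Potassium dicyanoaurate,13967-50-5,,,,,,,Nonbinder
Pyridine,110-86-1,Nonbinder,Sensitizer,LLNA,71.2,,,Nonbinder
Pyrogallol,87-66-1,,Sensitizer,LLNA,0.4 to 1.4,,,Binder
R-Carvone,6485-40-1,Binder,Sensitizer,LLNA,12.9,,,Binder
Resorcinol,108-46-3,Nonbinder,Sensitizer,LLNA,5.92,,,Nonbinder
Saccharin,81-07-2,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
Sodium dodecyl sulfate,151-21-3,Inconclusive,Sensitizer,LLNA,14,,,Nonbinder
Sodium metasilicate,6834-92-0,,Nonsensitizer,LLNA,2 to 6,,,Inconclusive
Sodium octyl sulfate,142-31-4,,,,,,,Nonbinder
Squaric acid,2892-51-5,Binder,Sensitizer,LLNA,4.3,,,Binder
Streptomycin sulfate,3810-74-0,Nonbinder,Nonsensitizer,LLNA,,,,Binder
Sulfanilamide,63-74-1,Nonbinder,Nonsensitizer,LLNA,,,,Nonbinder
Tetraethylthiuramdisulfide,97-77-8,,Sensitizer,LLNA,5.2,,,Binder
Tetramethylthiuram disulfide,137-26-8,Binder,Sensitizer,LLNA,3.1,,,Binder
Tetramethylthiurammonosulfide,97-74-5,,Sensitizer,LLNA,5.4,,,Binder
trans-2-Hexenal,6728-26-3,Binder,Sensitizer,LLNA,5.5,,,Binder
trans-p-Hydroxycinnamic acid,501-98-4,,,,,,,Binder
Triethanolamine,102-71-6,,Nonsensitizer,GPMT,,,,Binder
Trimethylolpropane triacrylate,15625-89-5,,Sensitizer,LLNA,0.01 to 0.13,,,Inconclusive
Tri-n-octylphosphine oxide,78-50-2,,,,,,,Binder
Triphenyl phosphate,115-86-6,,Sensitizer,GPMT,,,,Nonbinder
Tween 80,9005-65-6,Nonbinder,Nonsensitizer,LLNA,,,,Binder
Vanillin,121-33-5,Inconclusive,Nonsensitizer,LLNA,,,,Binder
Zinc diethyldithiocarbamate,14324-55-1,,Sensitizer,LLNA,0.2,,,Binder
α-Hexylcinnamaldehyde,101-86-0,Nonbinder,Sensitizer,LLNA,12,,,Binder
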