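name,group,mw,precursor_mz,fragments,rt,presence
Malic acid,Organic acids,134.0578,133.12,115.31;89.30;71.22,0.654,+/+
Dehydroascorbic acid,Vitamin and vitamin derivatives,174.0165,173.01,155.22;111.31;87.20;85.23,0.836,+/-
L-ascorbic acid,Vitamin and vitamin derivatives,176.0685,175.05,131.01;115.20;113.10;87.42,1.584,+/-
Caffeic acid,Phenolic acids,180.0423,179.04,135.11;107.21;91.10,11.856,+/+
Gallic acid monohydrate,Phenolic acids,188.0321,187.16,169.24;125.40;97.45,4.781,+/-
Citric acid,Organic acids,192.0271,191.12,173.42;129.40;111.22,0.737,+/+
Tryptophan,Amino acids,204.0899,203.16,186.61;142.32;116.33,1.335,+/-
(-) Epicatechin,Proanthocyanidins,290.2681,289.20,245.80;205.50;203.21;179.60;109.12,1.671,+/+
Salidroside,Phenolic glycosides,300.0852,299.27,179.54;137.00;89.43,1.062,-/+
Ellagic acid aglycone,Phenolic acids,302.0067,301.31,300.51;284.52;257.51;229.53;200.34,4.101,+/+
Coumaric acid hexose,Phenolic acids,326.1011,325.24,163.42;145.31,1.855,+/-
Galloyl hexose,Phenolic acids,332.0752,331.10,169.31;123.50,0.837,-/+
Coumaroylquinic acid,Phenolic acids,338.1013,337.27,191.52;173.50,4.100,-/+
Caffeic acid hexoside,Phenolic acids,342.0951,341.32,179.31;161.30;135.12,0.611,+/+
Galloylquinic acid,Phenolic acids,344.0753,343.23,191.00;169.61;93.42,0.800,-/+
p-Coumaroyl-ester,Phenolic acids,356,355.24,295.91;193.41;175.10;134.51,3.486,-/+
Dihydroferulic acid 4-O-glucuronide,Hydroxycinnamic acids,372.1056,371.31,209.82;193.51,3.564,-/+
Apigenin-7-O-glucoside,Flavonols,432.3775,431.28,270.82;269.54;225.22,2.927,+/-
Phloridzin,Flavonoid glycosides,436.1369,435.24,273.51;167.33;125.23,5.061,+/+
Ellagic acid deoxyhexoside,Hydroxycinnamic acid derivatives,448.0641,447.29,302.20;301.50;300.51;257.52;229.51,3.892,+/+
Ferulic acid hexose derivative,Hydroxycinnamic acids,450,449.29,355.61;287.52;269.52;193.83,3.147,+/-
Kaempferol glucuronide,Flavonols,462.3604,461.25,285.50;257.51;229.60;175.60;163.51;113.21,4.609,+/-
Quercetin hexoside,Flavonoid glycosides,464.3763,463.53,300.50;271.61;255.72;179.52,4.232,+/-
Sesquiterpenoid,Terpenoids and related compounds,464.2628,463.55,417.81;255.51;161.31,5.308,+/-
Kaempferol hexose,Flavonols,466.1118,465.28,447.30;285.62;241.63;151.40,3.333,-/+
Di-coumaroyl hexose,Hydroxycinnamic acid derivatives,472.1383,471.24,163.52;145.31,5.236,-/+
Quercetin-3-glucuronide,Flavonoid glycosides,478.3598,477.27,301.63;255.71;179.51;151.34;121.30,4.253,+/+
Sapogenin,Terpenoids and related compounds,488.3515,487.54,469.81;407.80;135.51,6.451,+/-
Kaempferol acetyl glucoside,Flavonols,490.4136,489.28,447.93;285.62;255.42,4.957,+/-
Octadecatrienoic acid glycoside,Fatty acid derivatives,560.3221,559.47,513.90;277.71;253.71;161.50,7.670,-/+
Dicaffeoylquinic acid,Phenolic acids,562.2996,561.61,515.30;191.82;161.42,6.961,+/-
Flavan-3-ol derivative,Proanthocyanidins,578.1647,577.27,425.94;407.82;289.60;269.51;147.60,3.374,+/+
Kaempferol coumaroyl hexoside,Flavonols,594.5196,593.34,447.52;285.84;255.41,6.126,+/+
Kaempferol-rutinoside,Flavonols,594.1585,593.12,547.53;327.51;308.80;285.60,6.111,+/-
Kaempferol pentose glucuronide,Flavonols,594.1244,593.24,307.63;285.62;113.31,6.008,-/+
Q-rutinoside,Flavonoid glycosides,610.1533,609.26,301.50;179.41;151.42,3.856,-/+
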