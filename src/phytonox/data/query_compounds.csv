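id,formula,smiles,reported_prediction
Epicatechin,C15H14O6,O[C@H]1CC2=C(O)C=C(O)C=C2O[C@H]1C1=CC(O)=C(O)C=C1,Active
Apigenin-7-O-glucoside,C21H20O10,OCC1OC(OC2=CC(O)=C3C(=O)C=C(OC3=C2)C2=CC=C(O)C=C2)C(O)C(O)C1O,Active
Sesquiterpenoid,C15H18O3,C[C@@H]1[C@@H]2CC[C@]3(C)C=CC(=O)C(C)=C3[C@@H]2OC1=O,Not Active
Sapogenin,C30H50O3,C[C@H]1CC[C@@]2([C@H]([C@H]3[C@@H](O2)C[C@@H]4[C@@]3(CC[C@H]5[C@H]4CCC6[C@@]5(CCCC6)C)C)C)OC1,Active
Salidroside,C14H20O7,OCC1OC(OCCC2=CC=C(O)C=C2)C(O)C(O)C1O,Active
Quercetin-3-glucuronide,C21H18O13,OC1C(O)C(OC2=C(OC3=CC(O)=CC(O)=C3C2=O)C2=CC=C(O)C(O)=C2)OC(C1O)C(O)=O,Active
Procyanidin dimer,C30H26O12,[H][C@]1([C@@H](O)[C@H](OC2=CC(O)=CC(O)=C12)C1=CC(O)=C(O)C=C1)C1=C2O[C@@H]([C@H](O)[C@@]([H])(C3=C(O)C=C(O)C4=C3O[C@@H]([C@H](O)C4)C3=CC(O)=C(O)C=C3)C2=C(O)C=C1O)C1=CC(O)=C(O)C=C1,Active
p-Coumaroyl-ester,C16H14O5,O[C@@H]1C[C@](O)(C[C@@H](OC(=O)\C=C/C2=CC=C(O)C(O)=C2)[C@@H]1O)C(O)=O,Active
Malic acid,C4H6O5,OC(CC(O)=O)C(O)=O,Not Active
L-ascorbic acid,C6H8O6,OCC(O)C1OC(=O)C(O)=C1O,Active
Kaempferol,C15H12O6,OC1=CC=C(C=C1)C1=C(O)C(=O)C2=C(O1)C=C(O)C=C2O,Active
Kaempferol acetylhexose,C23H22O12,OCC1OC(OC2C(O)C(O)C(CO)OC2OC2=C(OC3=CC(OC4OC(C(O)C(O)C4O)C(O)=O)=CC(O)=C3C2=O)C2=CC=C(O)C=C2)C(O)C(O)C1O,Active
Isorhamnetin hexose,C22H20O12,COC1=C(OC2OC(CO)C(O)C(O)C2O)C=CC(=C1)C1=C(O)C(=O)C2=C(O)C=C(O)C=C2O1,Active
Galloylquinic acid,C16H12O10,OS(=O)(=O)OC(=O)C1=CC=CC=C1,Active
Gallic acid monohydrate,C7H6O5,C(O)(=O)C1=CC(O)=C(O)C(O)=C1.[H]O[H],Active
Ellagic acid deoxyhexose,C20H16O12,OC1=CC=C(\C=C\C2=CC(O)=CC(O)=C2)C=C1,Active
Ellagic acid,C14H6O8,OC1=C(O)C2=C3C(=C1)C(=O)OC1=C3C(=CC(O)=C1O)C(=O)O2,Active
Dicaffeoylquinic acid,C25H24O12,O[C@H]1[C@H](OC(=O)\C=C\C2=CC=C(O)C(O)=C2)C[C@@](O)(C[C@H]1OC(=O)\C=C\C1=CC=C(O)C(O)=C1)C(=O)O,Active
Dehydroascorbic acid,C6H6O6,[H][C@@]1(OC(=O)C(=O)C1=O)[C@@H](O)CO,Not Active
Coumaroylquinic acid,C16H16O9,O[C@@H]1C[C@@](O)(C[C@@H](OC(=O)\C=C\C2=CC=C(O)C=C2)[C@H]1O)C(O)=O,Active
Citric acid,C6H8O7,OC(=O)CC(O)(CC(O)=O)C(O)=O,Not Active
Catechin,C15H14O6,O[C@H]1CC2=C(O)C=C(O)C=C2O[C@@H]1C1=CC(O)=C(O)C=C1,Active
Caffeic acid,C9H8O4,OC(=O)\C=C\C1=CC(O)=C(O)C=C1,Active
Tryptophan,C11H12N2O2,NC(CC1=CNC2=C1C=CC=C2)C(O)=O,Active
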