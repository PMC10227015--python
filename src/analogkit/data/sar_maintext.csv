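id,parent,field,value,comparator,units,provenance
masitinib,,delta_tm,7.4,=,degC,main text: dCK thermal stabilization by masitinib (TSA)
masitinib,,kd,1400,=,nM,main text: 1.4 uM dissociation constant for masitinib (ITC)
masitinib,,selectivity_ratio_il3_scf,100,>,ratio,main text: IL3/SCF IC50 ratio more than 100 for masitinib
dCKi1,masitinib,delta_tm,14.3,=,degC,main text: 14.3 degC thermal stabilization for dCKi1
dCKi1,masitinib,kd,128,=,nM,main text: KD 128 nM for dCKi1 (ITC)
dCKi1,masitinib,cellular_ic50,6900,=,nM,main text: CCRF-CEM proliferation IC50 6.9 uM for dCKi1
dCKi1,masitinib,selectivity_ratio_il3_scf,7.6,=,ratio,main text: IL3/SCF ratio 7.6 for dCKi1
dCKi2,masitinib,delta_tm,17.3,=,degC,main text: 17.3 degC thermal stabilization for dCKi2
dCKi2,masitinib,kd,37,=,nM,main text: KD 37 nM for dCKi2 (ITC)
dCKi2,masitinib,cellular_ic50,8900,=,nM,main text: CCRF-CEM proliferation IC50 8.9 uM for dCKi2
dCKi2,masitinib,selectivity_ratio_il3_scf,2.7,=,ratio,main text: IL3/SCF ratio 2.7 for dCKi2
OR0274,dCKi1,delta_tm,16.7,=,degC,main text: biphenyl C-D linker suppression; dTm +16.7 degC
OR0274,dCKi1,cellular_ic50,2096,=,nM,main text: cellular IC50 2096 nM for OR0274
OR0325,OR0274,delta_tm,17.8,=,degC,main text: D-E linker elongated by one carbon; dTm +17.8 degC
OR0325,OR0274,cellular_ic50,1676,=,nM,main text: cellular IC50 1676 nM for OR0325
OR0345,OR0325,delta_tm,18.4,=,degC,main text: N-propyl on B-C linker; dTm +18.4 degC
OR0345,OR0325,cellular_ic50,505,=,nM,main text: 3-fold decrease in cellular IC50 to 505 nM for OR0345
OR0600,OR0345,delta_tm,20.0,=,degC,main text: fusion analog of dCKi2 with dCKi1 optimizations; dTm +20 degC
OR0600,OR0345,cellular_ic50,341,=,nM,main text: improved cellular IC50 341 nM for OR0600
OR0602,OR0600,enzymatic_ic50,77,=,nM,main text: pyridine ring D; enzymatic IC50 77 nM at technical limit
OR0602,OR0600,cellular_ic50,130,=,nM,main text: cellular activity improved ~2.4-fold to IC50 130 nM
OR0624,OR0600,cellular_ic50,46,=,nM,main text: sulfonamide D-E linker; cellular IC50 improved >7-fold to 46 nM
OR0634,OR0602,cellular_ic50,54,=,nM,main text: hybrid of OR0602 and OR0624 modifications; cellular IC50 54 nM
OR0635,OR0634,delta_tm,20.4,=,degC,main text: OMe on ring D; dTm improved to +20.4 degC
OR0635,OR0634,cellular_ic50,15,=,nM,main text: cellular IC50 enhanced to 15 nM for OR0635
OR0642,OR0634,delta_tm,22.2,=,degC,main text: CF3 on ring D; dTm improved to +22.2 degC
OR0642,OR0634,cellular_ic50,2.2,=,nM,main text: cellular IC50 enhanced to 2.2 nM for OR0642 (lead)
OR0659,OR0642,delta_tm,6.3,=,degC,main text: negative control; lower binding affinity +6.3 degC
OR0659,OR0642,enzymatic_ic50,100000,>,nM,main text: negative control; enzymatic IC50 > 100 uM
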