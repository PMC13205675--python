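identifier,division,category
Col1a1,core matrisome,collagens
Col1a2,core matrisome,collagens
Col3a1,core matrisome,collagens
Col4a1,core matrisome,collagens
Col4a2,core matrisome,collagens
Acan,core matrisome,proteoglycans
Bgn,core matrisome,proteoglycans
Dcn,core matrisome,proteoglycans
Hspg2,core matrisome,proteoglycans
Vcan,core matrisome,proteoglycans
Fn1,core matrisome,glycoproteins
Lama1,core matrisome,glycoproteins
Lamb1,core matrisome,glycoproteins
Tgfbi,core matrisome,glycoproteins
Thbs4,core matrisome,glycoproteins
Adamts1,matrisome-associated,ECM regulators
Mmp2,matrisome-associated,ECM regulators
Mmp9,matrisome-associated,ECM regulators
Timp1,matrisome-associated,ECM regulators
Serpine1,matrisome-associated,ECM regulators
Anxa2,matrisome-associated,ECM-affiliated
Lgals1,matrisome-associated,ECM-affiliated
Lgals3,matrisome-associated,ECM-affiliated
Sdc1,matrisome-associated,ECM-affiliated
C1qa,matrisome-associated,ECM-affiliated
Ctgf,matrisome-associated,secreted factors
S100a8,matrisome-associated,secreted factors
Tgfb1,matrisome-associated,secreted factors
Wnt4,matrisome-associated,secreted factors
Fgf2,matrisome-associated,secreted factors
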