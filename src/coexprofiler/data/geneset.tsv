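symbol	categories	aliases	phenotype_class	source
Amh	phenotype		sexual_differentiation	review
Ar	nuclear_receptor			core
Ash2l	coregulator			core
Baz2a	methyltransferase			core
Bmp4	phenotype		embryonic_development	core
Bmp7	phenotype		sexual_differentiation	core
Bmp8a	phenotype		sexual_differentiation	core
Carm1	methyltransferase			review
Cxxc1	methyltransferase	Cfp1		core
Cyp17a1	phenotype		steroidogenesis	core
Dmrt1	phenotype		sexual_differentiation	core
Dmrt2	phenotype		sexual_differentiation	core
Dmrt3	phenotype		sexual_differentiation	core
Dmrta1	phenotype		sexual_differentiation	core
Dnmt1	methyltransferase			core
Dnmt3a	methyltransferase			review
Dnmt3b	methyltransferase			core
Dot1l	methyltransferase			review
Dpy30	coregulator			core
Ehmt1	methyltransferase	Glp		core
Ehmt2	methyltransferase	G9a		core
Esr1	nuclear_receptor			core
Esr2	nuclear_receptor			core
Ezh1	methyltransferase			review
Ezh2	methyltransferase			review
Fgf9	phenotype		sexual_differentiation	core
Hdac2	coregulator			core
Hoxa10	phenotype		embryonic_development	core
Hoxa11	phenotype		embryonic_development	core
Hoxa4	phenotype		embryonic_development	core
Hoxd3	phenotype		embryonic_development	core
Hoxd8	phenotype		embryonic_development	core
Insl3	phenotype		sexual_differentiation	core
Jag2	phenotype		sexual_differentiation	core
Jmjd6	demethylase			review
Kdm1	demethylase	Lsd1,Aof2,Kdm1a		core
Kdm2a	demethylase	Jhdm1a,Fbxl11		review
Kdm2b	demethylase	Jhdm1b,Fbxl10		core
Kdm3a	demethylase	Jmjd1a,Jhdm2a		core
Kdm3b	demethylase	Jmjd1b,Jhdm2b		review
Kdm4a	demethylase	Jmjd2a,Jhdm3a		review
Kdm4b	demethylase	Jmjd2b		review
Kdm4c	demethylase	Jmjd2c,Gasc1		review
Kdm4d	demethylase	Jmjd2d		review
Kdm5a	demethylase	Jarid1a,Rbp2		review
Kdm5b	demethylase	Jarid1b,Plu1		core
Kdm5c	demethylase	Jarid1c,Smcx		review
Kdm5d	demethylase	Jarid1d,Smcy		review
Kdm6a	demethylase	Utx		core
Kdm6b	demethylase	Jmjd3		core
Kdm8	demethylase	Jmjd5		review
Lep	phenotype		obesity	core
Lepr	phenotype		obesity	core
Leprot	phenotype		obesity	core
Men1	methyltransferase			core
Mll1	methyltransferase	Kmt2a,Mll		core
Mll2	methyltransferase	Kmt2b,Trx2		core
Mll3	methyltransferase	Kmt2c		core
Mll4	methyltransferase	Kmt2d		core
Mll5	methyltransferase	Kmt2e		core
Ncoa6	coregulator	Asc2,Prip,Rap250		core
Ncor2	coregulator			core
Nr0b1	nuclear_receptor;phenotype	Dax1	sexual_differentiation	review
Nr0b2	nuclear_receptor			review
Nr1d1	nuclear_receptor			review
Nr1d2	nuclear_receptor			core
Nr1h2	nuclear_receptor			core
Nr1h3	nuclear_receptor			review
Nr1h4	nuclear_receptor	Fxr		review
Nr2c1	nuclear_receptor	Tr2		core
Nr2c2	nuclear_receptor	Tr4		core
Nr2e1	nuclear_receptor			review
Nr2e3	nuclear_receptor			review
Nr2f1	nuclear_receptor			review
Nr2f2	nuclear_receptor			core
Nr2f6	nuclear_receptor			review
Nr3c1	nuclear_receptor	Gr		core
Nr3c2	nuclear_receptor			review
Nr4a1	nuclear_receptor			review
Nr4a2	nuclear_receptor			core
Nr4a3	nuclear_receptor			review
Nr5a1	nuclear_receptor;phenotype	Sf1	steroidogenesis	core
Nr5a2	nuclear_receptor			core
Nr6a1	nuclear_receptor	Gcnf		review
Nsd1	methyltransferase			review
Paxip1	methyltransferase			core
Pgr	nuclear_receptor			review
Phf8	demethylase			review
Ppara	nuclear_receptor			review
Ppard	nuclear_receptor			core
Pparg	nuclear_receptor			review
Prdm1	methyltransferase			review
Prdm16	methyltransferase			review
Prdm2	methyltransferase	Riz1		core
Prdm4	methyltransferase			review
Prdm5	methyltransferase			review
Prdm6	methyltransferase			review
Prdm9	methyltransferase			review
Prm1	phenotype		spermatogenesis	core
Prm2	phenotype		spermatogenesis	core
Prmt1	methyltransferase			review
Prmt5	methyltransferase			review
Prmt7	methyltransferase			review
Rara	nuclear_receptor			core
Rarb	nuclear_receptor			core
Rarg	nuclear_receptor			review
Rbbp5	coregulator			core
Rora	nuclear_receptor			core
Rorb	nuclear_receptor			review
Rorc	nuclear_receptor			review
Rxra	nuclear_receptor			review
Rxrb	nuclear_receptor			review
Rxrg	nuclear_receptor			review
Setd1a	methyltransferase			review
Setd1b	methyltransferase			review
Setd2	methyltransferase			review
Setd7	methyltransferase			review
Setd8	methyltransferase	Kmt5a		review
Setdb1	methyltransferase	Eset		core
Setdb2	methyltransferase			review
Shh	phenotype		sexual_differentiation	core
Smyd1	methyltransferase			review
Smyd2	methyltransferase			review
Smyd3	methyltransferase			review
Sox9	phenotype		sexual_differentiation	review
Sry	phenotype		sexual_differentiation	core
Star	phenotype		steroidogenesis	core
Suv39h1	methyltransferase			core
Suv39h2	methyltransferase			review
Suv420h1	methyltransferase			review
Suv420h2	methyltransferase			core
Thra	nuclear_receptor			review
Thrb	nuclear_receptor			review
Vdr	nuclear_receptor			review
Wdr5	coregulator			core
Whsc1	methyltransferase	Nsd2,Mmset		review
Whsc1l1	methyltransferase	Nsd3		review
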