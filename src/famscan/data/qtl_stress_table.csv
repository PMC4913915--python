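chromosome,qtl_name,position,stress,source
A02,SRA2,900158-10995801,Sclerotinia sclerotiorum,Wu et al.2013
A02,SRA2,3808580-20474897,Sclerotinia sclerotiorum,Wu et al.2013
A02,qSR10-1,390973-20984604,Sclerotinia sclerotiorum,Mei et al.2013
A02,LmA2,9629867-20463672,black leg,Delourme et al.2008
A02,Anju2,4840764-10251601,clubroot,Tomita et al.2013
A03,SRA3,5762514-29673240,Sclerotinia sclerotiorum,Wu et al.2013
A03,qSR10-2,606874-3131828,Sclerotinia sclerotiorum,Mei et al.2013
A06,SRA6,20965425-23324292,Sclerotinia sclerotiorum,Wu et al.2013
A08,SRA8,816774-18390028,Sclerotinia sclerotiorum,Wu et al.2013
A09,SRA9,2258676-26573318,Sclerotinia sclerotiorum,Wu et al.2013
A09,LmA9,17684286-25984575,black leg,Delourme et al.2008
C01,qLR09-3,12756747-21935046,Sclerotinia sclerotiorum,Mei et al.2013
C01,qLR10-1,12756747-21935046,Sclerotinia sclerotiorum,Mei et al.2013
C02,Anju1,42040597-44755227,clubroot,Tomita et al.2013
C02,LmC2.1,9837239-16325078,black leg,Delourme et al.2008
C02,QTL-1,358639-5209750,black rot,Kifuji et al.2013
C03,Anju3,1282758-8855466,clubroot,Tomita et al.2013
C03,QTL-3,411772-5820967,diamondback moth,Asghari et al.2009
C04,Sll14a,4910121-9418160,Sclerotinia sclerotiorum,Wu et al.2013
C05,LRC5,101013-30986806,Sclerotinia sclerotiorum,Wu et al.2013
C05,GC1,6768180-11801042,clubroot,Tomita et al.2013
C06,Sll16,7571202-35465622,Sclerotinia sclerotiorum,Wu et al.2013
C06,SRC6.1,31256776-36061993,Sclerotinia sclerotiorum,Wu et al.2013
C06,SRC6.2,24665572-35953761,Sclerotinia sclerotiorum,Wu et al.2013
C07,qSR10-2,23541376-36743363,Sclerotinia sclerotiorum,Mei et al.2013
C07,Anju4,35610814-37812010,clubroot,Tomita et al.2013
C07,QTL2(Foc-Bo1),36671239-39348306,Fusarium wilt,Pu et al.2011
C09,qSR09-1,2984476-5282988,Sclerotinia sclerotiorum,Mei et al.2013
C09,qSR-09-2,2387812-2861882,Sclerotinia sclerotiorum,Mei et al.2013
C09,qLR-09-6,2387812-3087435,Sclerotinia sclerotiorum,Mei et al.2013
C09,qSR10-3,2984476-5282988,Sclerotinia sclerotiorum,Mei et al.2013
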