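value,frequency
MARGARET,0.01601877
SUSAN,0.01377410
PATRICIA,0.01244771
JENNIFER,0.01214162
ELIZABETH,0.01071319
MARY,0.01049893
HELEN,0.01049893
DOROTHY,0.01049893
JOAN,0.01049893
BETTY,0.01049893
SHIRLEY,0.01049893
JUDITH,0.01049893
PAMELA,0.01049893
CAROL,0.01049893
SANDRA,0.01049893
CHRISTINE,0.01049893
JANET,0.01049893
BARBARA,0.01049893
LINDA,0.01049893
KAREN,0.01049893
DONNA,0.01049893
LISA,0.01049893
MICHELLE,0.01049893
AMANDA,0.01049893
NICOLE,0.01049893
REBECCA,0.01049893
JESSICA,0.01049893
EMILY,0.01049893
SARAH,0.01049893
EMMA,0.01049893
OLIVIA,0.01049893
CHLOE,0.01049893
SOPHIE,0.01049893
GRACE,0.01049893
HANNAH,0.01049893
ANNE,0.01049893
ANNA,0.01049893
JANE,0.01049893
CATHERINE,0.01020325
KATHERINE,0.00989750
KATHLEEN,0.00960891
FRANCES,0.00933611
JOSEPHINE,0.00907784
EILEEN,0.00883298
MAUREEN,0.00860054
LIZ,0.00837959
BETH,0.00816932
MAGGIE,0.00796899
SUE,0.00777790
PATTY,0.00759545
JENNY,0.00742107
KATE,0.00725423
KATHY,0.00709448
TRICIA,0.00694136
PEGGY,0.00679448
BECKY,0.00665347
JESS,0.00651800
MANDY,0.00638773
NIKKI,0.00626239
CHRIS,0.00614171
TINA,0.00602542
VICKY,0.00591330
DEBBIE,0.00580513
CINDY,0.00570071
SALLY,0.00559984
ALICE,0.00550236
CLARA,0.00540809
EDITH,0.00531689
ETHEL,0.00522860
FLORENCE,0.00514310
GLADYS,0.00506024
HILDA,0.00497992
IRENE,0.00490202
MABEL,0.00482643
NORA,0.00475306
RUTH,0.00468180
EVELYN,0.00461257
VERA,0.00454529
VIOLET,0.00447988
WINIFRED,0.00441625
DAPHNE,0.00435434
GWENDOLYN,0.00429408
MURIEL,0.00423540
SYLVIA,0.00417825
THELMA,0.00412257
FIONA,0.00406830
BRONWYN,0.00401539
NARELLE,0.00396379
KYLIE,0.00391345
HAYLEY,0.00386433
TANYA,0.00381638
SHARON,0.00376956
TRACEY,0.00372384
LEANNE,0.00367917
RAELENE,0.00363553
SIOBHAN,0.00359287
AISLING,0.00355116
NIAMH,0.00351038
MAEVE,0.00347049
BRIDGET,0.00343146
CAITLIN,0.00339327
ERIN,0.00335589
SHANNON,0.00331930
KERRY,0.00328346
CLODAGH,0.00324837
INGRID,0.00321399
GRETA,0.00318030
HEIDI,0.00314729
URSULA,0.00311493
HELGA,0.00308320
ASTRID,0.00305209
FREYA,0.00302158
SIGRID,0.00299165
ANNELIESE,0.00296229
LISELOTTE,0.00293348
MARIA,0.00290520
SOFIA,0.00287745
GIULIA,0.00285020
FRANCESCA,0.00282344
CHIARA,0.00279716
VALENTINA,0.00277135
ELENA,0.00274599
LUCIA,0.00272108
PAOLA,0.00269660
ROSA,0.00267254
ELENI,0.00264889
DESPINA,0.00262564
KATERINA,0.00260278
VASILIKI,0.00258029
GEORGIA,0.00255818
ATHINA,0.00253644
DIMITRA,0.00251504
IOANNA,0.00249399
SOFIA-MARIA,0.00247328
PANAGIOTA,0.00245290
LINH,0.00243283
HUONG,0.00241308
MAI,0.00239364
LAN,0.00237450
HOA,0.00235565
THU,0.00233708
NGOC,0.00231880
HANH,0.00230079
PHUONG,0.00228304
TUYET,0.00226556
MEI,0.00224833
LING,0.00223136
XIU,0.00221463
YAN,0.00219814
HUI,0.00218188
FANG,0.00216585
JING,0.00215005
LAN-YING,0.00213447
LI-NA,0.00211911
WEN,0.00210396
PRIYA,0.00208901
ANITA,0.00207427
SUNITA,0.00205973
KAVITA,0.00204538
REKHA,0.00203122
NEHA,0.00201725
POOJA,0.00200347
DEEPA,0.00198986
ASHA,0.00197643
LAKSHMI,0.00196318
CARMEN,0.00195010
ISABEL,0.00193718
LUCIA-MARIA,0.00192442
PILAR,0.00191183
ROSARIO,0.00189940
DOLORES,0.00188711
CONSUELO,0.00187499
MERCEDES,0.00186301
ESPERANZA,0.00185117
SOLEDAD,0.00183949
MARY ANNE,0.00182794
ANNE MARIE,0.00181653
JO ANNE,0.00180526
MARY JANE,0.00179412
SARAH JANE,0.00178311
MARY-ANNE,0.00177223
ANNE-MARIE,0.00176148
LEE-ANNE,0.00175086
JO-ANNE,0.00174035
KYLIE-ANNE,0.00172997
RUBY,0.00171971
PEARL,0.00170956
OPAL,0.00169953
HAZEL,0.00168961
IVY,0.00167980
DAISY,0.00167010
POPPY,0.00166051
ROSE,0.00165102
LILY,0.00164164
VIOLET-MAY,0.00163236
ADELAIDE,0.00162318
BEATRICE,0.00161410
CECILIA,0.00160512
DELIA,0.00159623
EUGENIA,0.00158743
FELICITY,0.00157873
GENEVIEVE,0.00157012
HARRIET,0.00156160
IMOGEN,0.00155317
JULIET,0.00154483
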