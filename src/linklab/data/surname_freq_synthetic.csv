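value,frequency
SMITH,0.00938584
JONES,0.00561110
BROWN,0.00469292
WILLIAMS,0.00469292
TAYLOR,0.00448888
WILSON,0.00439910
ANDERSON,0.00439910
THOMPSON,0.00439910
JOHNSON,0.00439910
WHITE,0.00439910
MARTIN,0.00439910
THOMAS,0.00439910
WALKER,0.00439910
KELLY,0.00439910
YOUNG,0.00439910
HARRIS,0.00439910
KING,0.00439910
WRIGHT,0.00439910
SCOTT,0.00439910
DAVIES,0.00439910
EDWARDS,0.00439910
GREEN,0.00439910
ROBERTS,0.00439910
HALL,0.00439910
WOOD,0.00439910
CLARKE,0.00439910
ROBINSON,0.00439910
STEWART,0.00439910
MITCHELL,0.00439910
CAMPBELL,0.00439910
MOORE,0.00439910
TURNER,0.00439910
LEE,0.00439910
HILL,0.00439910
EVANS,0.00439910
ALLEN,0.00439910
BAKER,0.00439910
COLLINS,0.00439910
MURPHY,0.00439910
MURRAY,0.00439910
GRAHAM,0.00439910
BELL,0.00439910
RYAN,0.00439910
COOK,0.00439910
CARTER,0.00439910
PHILLIPS,0.00439910
ADAMS,0.00439910
MORRIS,0.00439910
GRAY,0.00439910
JAMES,0.00439910
WATSON,0.00439910
RUSSELL,0.00439910
MASON,0.00439910
HUGHES,0.00439910
PRICE,0.00439910
BENNETT,0.00439910
COOPER,0.00439910
RICHARDSON,0.00439910
COX,0.00439910
WARD,0.00439910
HOWARD,0.00439910
PETERSON,0.00439910
BAILEY,0.00439910
REED,0.00439910
FOSTER,0.00439910
POWELL,0.00439910
LONG,0.00439910
PARKER,0.00439910
BROOKS,0.00439910
HENDERSON,0.00439910
SIMPSON,0.00439910
PATTERSON,0.00439910
REYNOLDS,0.00439910
HAMILTON,0.00439910
FORD,0.00439910
GIBSON,0.00439910
WALLACE,0.00439910
GRANT,0.00439910
DIXON,0.00439910
HUNT,0.00439910
WEBB,0.00439910
TUCKER,0.00439910
PORTER,0.00439910
HARPER,0.00439910
FISHER,0.00439910
O'BRIEN,0.00439910
O'CONNOR,0.00439910
O'NEILL,0.00439910
O'SULLIVAN,0.00439910
MCDONALD,0.00439910
MCCARTHY,0.00439910
MCKENZIE,0.00439910
MCLEAN,0.00439910
MACDONALD,0.00439910
MCGRATH,0.00439910
FITZGERALD,0.00439910
GALLAGHER,0.00439910
DOHERTY,0.00439910
BRENNAN,0.00439910
BYRNE,0.00439910
DUFFY,0.00439910
FLYNN,0.00439910
KENNEDY,0.00439910
LYNCH,0.00439910
NOLAN,0.00439910
QUINN,0.00439910
REGAN,0.00439910
SHEEHAN,0.00439910
WALSH,0.00439910
BARRY,0.00439910
BURKE,0.00439910
CASEY,0.00439910
CONNOLLY,0.00439910
DALY,0.00439910
DONNELLY,0.00439910
SMYTH,0.00439910
SMYTHE,0.00439910
TAYLER,0.00439910
BROWNE,0.00439910
JOHNSTON,0.00439910
JOHNSTONE,0.00439910
CLARK,0.00439910
STUART,0.00439910
STEVENS,0.00439910
STEPHENS,0.00439910
MEYER,0.00438079
MULLER,0.00434234
SCHMIDT,0.00430453
WAGNER,0.00426735
WEBER,0.00423078
FISCHER,0.00419482
BECKER,0.00415943
HOFFMANN,0.00412462
SCHULZ,0.00409037
KOCH,0.00405665
ROSSI,0.00402347
RUSSO,0.00399081
FERRARI,0.00395866
ESPOSITO,0.00392700
BIANCHI,0.00389582
ROMANO,0.00386512
COLOMBO,0.00383488
RICCI,0.00380509
MARINO,0.00377574
GRECO,0.00374683
PAPADOPOULOS,0.00371834
GEORGIOU,0.00369027
DIMITRIOU,0.00366260
NIKOLAOU,0.00363533
ANGELOPOULOS,0.00360844
STAVROU,0.00358194
CHRISTOU,0.00355581
ECONOMOU,0.00353004
KATSAROS,0.00350463
VLAHOS,0.00347957
NGUYEN,0.00345486
TRAN,0.00343047
LE,0.00340642
PHAM,0.00338269
HOANG,0.00335928
VU,0.00333618
DANG,0.00331338
BUI,0.00329088
DO,0.00326867
HO,0.00324675
WONG,0.00322511
CHAN,0.00320375
LI,0.00318265
WANG,0.00316183
ZHANG,0.00314126
CHEN,0.00312095
LIU,0.00310089
LIN,0.00308108
HUANG,0.00306151
WU,0.00304218
SINGH,0.00302308
KAUR,0.00300422
PATEL,0.00298557
SHARMA,0.00296715
KUMAR,0.00294895
GUPTA,0.00293096
MEHTA,0.00291318
SHAH,0.00289561
VERMA,0.00287824
RAO,0.00286107
SANTOS,0.00284409
REYES,0.00282731
CRUZ,0.00281072
BAUTISTA,0.00279432
OCAMPO,0.00277809
RAMOS,0.00276205
GARCIA,0.00274619
MARTINEZ,0.00273050
LOPEZ,0.00271498
GONZALEZ,0.00269963
VAN DER BERG,0.00268445
VAN DIJK,0.00266943
DE VRIES,0.00265458
DE JONG,0.00263988
VAN DEN BERG,0.00262533
JANSEN,0.00261094
VISSER,0.00259670
BAKKER,0.00258261
MULDER,0.00256867
DEKKER,0.00255487
KOWALSKI,0.00254122
NOWAK,0.00252770
WISNIEWSKI,0.00251432
KAMINSKI,0.00250108
LEWANDOWSKI,0.00248797
ZIELINSKI,0.00247499
SZYMANSKI,0.00246214
WOJCIK,0.00244942
KOZLOWSKI,0.00243682
JANKOWSKI,0.00242435
IVANOV,0.00241200
PETROV,0.00239978
SMIRNOV,0.00238767
KUZNETSOV,0.00237568
POPOV,0.00236380
SOKOLOV,0.00235204
LEBEDEV,0.00234039
KOZLOV,0.00232885
NOVIKOV,0.00231742
MOROZOV,0.00230610
SMITH-JONES,0.00229488
TAYLOR-BROWN,0.00228377
WILSON-SMITH,0.00227276
ANDERSON-LEE,0.00226185
HARRIS-WHITE,0.00225104
ABBOTT,0.00224034
AHERN,0.00222972
AINSWORTH,0.00221921
ALCOCK,0.00220879
ALDRIDGE,0.00219847
ALLAN,0.00218823
ANSTEY,0.00217809
APPLEBY,0.00216804
ARCHER,0.00215808
ARMSTRONG,0.00214821
ATKINS,0.00213842
ATKINSON,0.00212872
AUSTIN,0.00211910
AYRES,0.00210956
BACON,0.00210011
BADGER,0.00209074
BAGLEY,0.00208145
BALDWIN,0.00207224
BALL,0.00206311
BANKS,0.00205405
BARBER,0.00204507
BARCLAY,0.00203617
BARKER,0.00202734
BARLOW,0.00201858
BARNES,0.00200989
BARNETT,0.00200128
BARRETT,0.00199274
BARTON,0.00198427
BATES,0.00197587
BAXTER,0.00196753
BEATTIE,0.00195926
BECK,0.00195106
BEDFORD,0.00194293
BEECH,0.00193486
BELCHER,0.00192686
BENSON,0.00191891
BENTLEY,0.00191104
BERRY,0.00190322
BEST,0.00189546
BEVAN,0.00188777
BICKFORD,0.00188013
BIRD,0.00187256
BISHOP,0.00186504
BLACK,0.00185758
BLACKWELL,0.00185018
BLAIR,0.00184284
BLAKE,0.00183555
BOLTON,0.00182831
BOND,0.00182113
BOOTH,0.00181401
BOWEN,0.00180694
BOWMAN,0.00179992
BOYD,0.00179295
BRADLEY,0.00178604
BRADSHAW,0.00177917
BRAMBLE,0.00177236
BRAND,0.00176560
BRAY,0.00175888
BREWER,0.00175222
BRIGGS,0.00174560
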