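value,frequency
JOHN,0.03509846
DAVID,0.03152740
MICHAEL,0.03009897
PETER,0.02928273
ROBERT,0.02520151
JAMES,0.02469748
WILLIAM,0.02469748
RICHARD,0.02469748
THOMAS,0.02469748
CHRISTOPHER,0.02469748
PAUL,0.02469748
MARK,0.02469748
ANDREW,0.02469748
STEPHEN,0.02393655
GRAHAM,0.02159521
ANTHONY,0.01965829
KEVIN,0.01803029
BRIAN,0.01664345
GARY,0.01544838
IAN,0.01440828
COLIN,0.01349512
ALAN,0.01268724
RAYMOND,0.01196762
GEOFFREY,0.01132268
BARRY,0.01074150
DANIEL,0.01021516
MATTHEW,0.00973634
LUKE,0.00929894
JOSHUA,0.00889788
BENJAMIN,0.00852885
SAMUEL,0.00818821
JACOB,0.00787283
NATHAN,0.00758004
ADAM,0.00730753
RYAN,0.00705328
GEORGE,0.00681553
EDWARD,0.00659275
HENRY,0.00638358
ALBERT,0.00618683
ARTHUR,0.00600143
FREDERICK,0.00582645
ERNEST,0.00566103
HAROLD,0.00550442
STANLEY,0.00535595
LEONARD,0.00521501
BILL,0.00508104
BOB,0.00495354
JIM,0.00483206
TOM,0.00471620
MIKE,0.00460557
DAVE,0.00449983
STEVE,0.00439867
RICK,0.00430180
TONY,0.00420895
FRED,0.00411989
HARRY,0.00403439
JACK,0.00395224
ALEX,0.00387326
SAM,0.00379726
BEN,0.00372408
DAN,0.00365356
NICK,0.00358558
ROB,0.00351999
WILL,0.00345667
TED,0.00339551
DICK,0.00333640
RON,0.00327924
DON,0.00322394
KEN,0.00317041
NEIL,0.00311856
ROSS,0.00306832
WAYNE,0.00301962
DEAN,0.00297238
GLEN,0.00292655
BRETT,0.00288206
SCOTT,0.00283885
SHANE,0.00279687
TROY,0.00275608
CRAIG,0.00271641
DARREN,0.00267783
JASON,0.00264029
TRAVIS,0.00260375
KYLE,0.00256817
BRADLEY,0.00253352
LACHLAN,0.00249976
ANGUS,0.00246685
DOUGLAS,0.00243477
DUNCAN,0.00240348
GORDON,0.00237295
MALCOLM,0.00234317
STUART,0.00231409
KEITH,0.00228571
NORMAN,0.00225798
ROGER,0.00223090
TERENCE,0.00220443
PATRICK,0.00217857
SEAN,0.00215328
LIAM,0.00212855
CONNOR,0.00210436
DECLAN,0.00208070
BRENDAN,0.00205754
DAMIEN,0.00203487
FINN,0.00201268
RORY,0.00199096
KIERAN,0.00196967
CARL,0.00194883
ERIC,0.00192840
FRANK,0.00190838
HANS,0.00188876
KARL,0.00186952
OTTO,0.00185066
WALTER,0.00183216
WERNER,0.00181402
GUNTER,0.00179621
STEFAN,0.00177874
MARIO,0.00176160
LUIGI,0.00174476
ANTONIO,0.00172824
GIUSEPPE,0.00171202
GIOVANNI,0.00169608
FRANCO,0.00168043
CARLO,0.00166506
ENZO,0.00164995
PAOLO,0.00163511
MARCO,0.00162052
DIMITRI,0.00160618
NIKOS,0.00159208
YANNIS,0.00157821
COSTAS,0.00156458
SPIRO,0.00155118
THEO,0.00153799
STAVROS,0.00152502
PETROS,0.00151225
ANDREAS,0.00149969
GEORGIOS,0.00148733
MINH,0.00147517
DUC,0.00146319
QUANG,0.00145140
HUY,0.00143980
THANH,0.00142837
TUAN,0.00141711
ANH,0.00140602
HAI,0.00139510
LONG,0.00138434
NAM,0.00137374
WEI,0.00136330
JUN,0.00135300
MING,0.00134286
HAO,0.00133286
LEI,0.00132300
CHENG,0.00131328
KAI,0.00130370
JIAN,0.00129426
FENG,0.00128494
YONG,0.00127575
RAJ,0.00126669
ARJUN,0.00125775
ROHIT,0.00124893
SANJAY,0.00124023
VIJAY,0.00123165
ANIL,0.00122318
SUNIL,0.00121482
RAVI,0.00120657
DEEPAK,0.00119843
AMIT,0.00119039
JOSE,0.00118246
JUAN,0.00117462
CARLOS,0.00116689
MIGUEL,0.00115925
PEDRO,0.00115171
LUIS,0.00114427
DIEGO,0.00113691
FERNANDO,0.00112965
RICARDO,0.00112248
PABLO,0.00111539
OLIVER,0.00110839
ETHAN,0.00110147
NOAH,0.00109463
LUCAS,0.00108788
MASON,0.00108120
LOGAN,0.00107461
CALEB,0.00106809
ISAAC,0.00106165
LEVI,0.00105528
FELIX,0.00104898
ROY,0.00104276
LES,0.00103661
STAN,0.00103052
BERT,0.00102451
ALF,0.00101856
CLIVE,0.00101268
CECIL,0.00100686
CYRIL,0.00100111
HERBERT,0.00099542
HORACE,0.00098980
MAXWELL,0.00098423
MURRAY,0.00097872
LINDSAY,0.00097328
BRUCE,0.00096789
TREVOR,0.00096255
NIGEL,0.00095728
RODNEY,0.00095206
CLIFFORD,0.00094689
LLOYD,0.00094178
VERNON,0.00093672
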