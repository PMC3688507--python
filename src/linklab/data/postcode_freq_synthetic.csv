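value,frequency
6210,0.02868977
6163,0.02353773
6027,0.02081018
6155,0.02040610
6065,0.02020406
6000,0.01979998
6001,0.01979998
6002,0.01979998
6003,0.01979998
6004,0.01912078
6005,0.01716496
6006,0.01563322
6007,0.01439599
6008,0.01337246
6009,0.01250940
6010,0.01177022
6011,0.01112887
6012,0.01056627
6013,0.01006810
6014,0.00962338
6015,0.00922353
6016,0.00886177
6017,0.00853265
6018,0.00823172
6019,0.00795533
6020,0.00770044
6021,0.00746452
6022,0.00724542
6023,0.00704131
6024,0.00685062
6025,0.00667201
6026,0.00650430
6028,0.00634648
6029,0.00619764
6030,0.00605701
6031,0.00592388
6032,0.00579765
6033,0.00567775
6034,0.00556370
6035,0.00545506
6036,0.00535143
6037,0.00525246
6038,0.00515782
6039,0.00506722
6040,0.00498038
6041,0.00489708
6042,0.00481708
6043,0.00474018
6044,0.00466619
6045,0.00459495
6046,0.00452630
6047,0.00446008
6048,0.00439617
6049,0.00433443
6050,0.00427477
6051,0.00421705
6052,0.00416120
6053,0.00410711
6054,0.00405469
6055,0.00400387
6056,0.00395457
6057,0.00390672
6058,0.00386025
6059,0.00381510
6060,0.00377121
6061,0.00372853
6062,0.00368700
6063,0.00364658
6064,0.00360722
6066,0.00356887
6067,0.00353150
6068,0.00349506
6069,0.00345953
6070,0.00342486
6071,0.00339102
6072,0.00335798
6073,0.00332572
6074,0.00329419
6075,0.00326339
6076,0.00323327
6077,0.00320382
6078,0.00317501
6079,0.00314682
6080,0.00311924
6081,0.00309223
6082,0.00306579
6083,0.00303988
6084,0.00301450
6085,0.00298964
6086,0.00296526
6087,0.00294136
6088,0.00291792
6089,0.00289493
6090,0.00287238
6091,0.00285025
6092,0.00282852
6093,0.00280720
6094,0.00278626
6095,0.00276570
6096,0.00274550
6097,0.00272566
6098,0.00270616
6099,0.00268699
6100,0.00266816
6101,0.00264964
6102,0.00263143
6103,0.00261352
6104,0.00259590
6105,0.00257857
6106,0.00256152
6107,0.00254474
6108,0.00252822
6109,0.00251196
6110,0.00249595
6111,0.00248019
6112,0.00246467
6113,0.00244938
6114,0.00243432
6115,0.00241949
6116,0.00240487
6117,0.00239046
6118,0.00237626
6119,0.00236226
6120,0.00234847
6121,0.00233486
6122,0.00232145
6123,0.00230822
6124,0.00229518
6125,0.00228231
6126,0.00226961
6127,0.00225709
6128,0.00224473
6129,0.00223254
6130,0.00222050
6131,0.00220862
6132,0.00219690
6133,0.00218532
6134,0.00217389
6135,0.00216261
6136,0.00215146
6137,0.00214046
6138,0.00212959
6139,0.00211885
6140,0.00210825
6141,0.00209777
6142,0.00208742
6143,0.00207719
6144,0.00206708
6145,0.00205709
6146,0.00204722
6147,0.00203746
6148,0.00202781
6149,0.00201828
6150,0.00200885
6151,0.00199953
6152,0.00199031
6153,0.00198120
6154,0.00197218
6156,0.00196327
6157,0.00195445
6158,0.00194573
6159,0.00193710
6160,0.00192856
6161,0.00192012
6162,0.00191176
6164,0.00190349
6165,0.00189531
6166,0.00188721
6167,0.00187920
6168,0.00187127
6169,0.00186342
6170,0.00185565
6171,0.00184795
6172,0.00184034
6173,0.00183280
6174,0.00182533
6175,0.00181794
6176,0.00181062
6177,0.00180337
6178,0.00179619
6179,0.00178908
6180,0.00178204
6181,0.00177507
6182,0.00176816
6183,0.00176131
6184,0.00175453
6185,0.00174782
6186,0.00174116
6187,0.00173457
6188,0.00172803
6189,0.00172156
6190,0.00171515
6191,0.00170879
6192,0.00170249
6193,0.00169624
6194,0.00169005
6195,0.00168392
6196,0.00167784
6197,0.00167181
6198,0.00166584
6199,0.00165991
6200,0.00165404
6201,0.00164822
6202,0.00164244
6203,0.00163672
6204,0.00163104
6205,0.00162541
6206,0.00161983
6207,0.00161430
6208,0.00160881
6209,0.00160336
6211,0.00159796
6212,0.00159261
6213,0.00158730
6214,0.00158203
6215,0.00157680
6216,0.00157161
6217,0.00156647
6218,0.00156137
6219,0.00155630
6220,0.00155128
6221,0.00154629
6222,0.00154135
6223,0.00153644
6224,0.00153157
6225,0.00152674
6226,0.00152194
6227,0.00151718
6228,0.00151246
6229,0.00150777
6744,0.00150312
6676,0.00149850
6385,0.00149392
6446,0.00148937
6679,0.00148485
6371,0.00148037
6692,0.00147592
6327,0.00147150
6375,0.00146711
6455,0.00146276
6315,0.00145844
6574,0.00145414
6495,0.00144988
6273,0.00144565
6636,0.00144145
6691,0.00143728
6287,0.00143313
6288,0.00142902
6338,0.00142494
6245,0.00142088
6733,0.00141685
6522,0.00141285
6464,0.00140887
6477,0.00140493
6322,0.00140101
6650,0.00139711
6507,0.00139324
6396,0.00138940
6231,0.00138559
6547,0.00138179
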