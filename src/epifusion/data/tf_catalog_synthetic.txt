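TF0001
TF0002
TF0003
TF0004
TF0005
TF0006
TF0007
TF0008
TF0009
TF0010
TF0011
TF0012
TF0013
TF0014
TF0015
TF0016
TF0017
TF0018
TF0019
TF0020
TF0021
TF0022
TF0023
TF0024
TF0025
TF0026
TF0027
TF0028
TF0029
TF0030
TF0031
TF0032
TF0033
TF0034
TF0035
TF0036
TF0037
TF0038
TF0039
TF0040
TF0041
TF0042
TF0043
TF0044
TF0045
TF0046
TF0047
TF0048
TF0049
TF0050
TF0051
TF0052
TF0053
TF0054
TF0055
TF0056
TF0057
TF0058
TF0059
TF0060
TF0061
TF0062
TF0063
TF0064
TF0065
TF0066
TF0067
TF0068
TF0069
TF0070
TF0071
TF0072
TF0073
TF0074
TF0075
TF0076
TF0077
TF0078
TF0079
TF0080
TF0081
TF0082
TF0083
TF0084
TF0085
TF0086
TF0087
TF0088
TF0089
TF0090
TF0091
TF0092
TF0093
TF0094
TF0095
TF0096
TF0097
TF0098
TF0099
TF0100
TF0101
TF0102
TF0103
TF0104
TF0105
TF0106
TF0107
TF0108
TF0109
TF0110
TF0111
TF0112
TF0113
TF0114
TF0115
TF0116
TF0117
TF0118
TF0119
TF0120
TF0121
TF0122
TF0123
TF0124
TF0125
TF0126
TF0127
TF0128
TF0129
TF0130
TF0131
TF0132
TF0133
TF0134
TF0135
TF0136
TF0137
TF0138
TF0139
TF0140
TF0141
TF0142
TF0143
TF0144
TF0145
TF0146
TF0147
TF0148
TF0149
TF0150
TF0151
TF0152
TF0153
TF0154
TF0155
TF0156
TF0157
TF0158
TF0159
TF0160
TF0161
TF0162
TF0163
TF0164
TF0165
TF0166
TF0167
TF0168
TF0169
TF0170
TF0171
TF0172
TF0173
TF0174
TF0175
TF0176
TF0177
TF0178
TF0179
TF0180
TF0181
TF0182
TF0183
TF0184
TF0185
TF0186
TF0187
TF0188
TF0189
TF0190
TF0191
TF0192
TF0193
TF0194
TF0195
TF0196
TF0197
TF0198
TF0199
TF0200
TF0201
TF0202
TF0203
TF0204
TF0205
TF0206
TF0207
TF0208
TF0209
TF0210
TF0211
TF0212
TF0213
TF0214
TF0215
TF0216
TF0217
TF0218
TF0219
TF0220
TF0221
TF0222
TF0223
TF0224
TF0225
TF0226
TF0227
TF0228
TF0229
TF0230
TF0231
TF0232
TF0233
TF0234
TF0235
TF0236
TF0237
TF0238
TF0239
TF0240
TF0241
TF0242
TF0243
TF0244
TF0245
TF0246
TF0247
TF0248
TF0249
TF0250
TF0251
TF0252
TF0253
TF0254
TF0255
TF0256
TF0257
TF0258
TF0259
TF0260
TF0261
TF0262
TF0263
TF0264
TF0265
TF0266
TF0267
TF0268
TF0269
TF0270
TF0271
TF0272
TF0273
TF0274
TF0275
TF0276
TF0277
TF0278
TF0279
TF0280
TF0281
TF0282
TF0283
TF0284
TF0285
TF0286
TF0287
TF0288
TF0289
TF0290
TF0291
TF0292
TF0293
TF0294
TF0295
TF0296
TF0297
TF0298
TF0299
TF0300
TF0301
TF0302
TF0303
TF0304
TF0305
TF0306
TF0307
TF0308
TF0309
TF0310
TF0311
TF0312
TF0313
TF0314
TF0315
TF0316
TF0317
TF0318
TF0319
TF0320
TF0321
TF0322
TF0323
TF0324
TF0325
TF0326
TF0327
TF0328
TF0329
TF0330
TF0331
TF0332
TF0333
TF0334
TF0335
TF0336
TF0337
TF0338
TF0339
TF0340
TF0341
TF0342
TF0343
TF0344
TF0345
TF0346
TF0347
TF0348
TF0349
TF0350
TF0351
TF0352
TF0353
TF0354
TF0355
TF0356
TF0357
TF0358
TF0359
TF0360
TF0361
TF0362
TF0363
TF0364
TF0365
TF0366
TF0367
TF0368
TF0369
TF0370
TF0371
TF0372
TF0373
TF0374
TF0375
TF0376
TF0377
TF0378
TF0379
TF0380
TF0381
TF0382
TF0383
TF0384
TF0385
TF0386
TF0387
TF0388
TF0389
TF0390
TF0391
TF0392
TF0393
TF0394
TF0395
TF0396
TF0397
TF0398
TF0399
TF0400
TF0401
TF0402
TF0403
TF0404
TF0405
TF0406
TF0407
TF0408
TF0409
TF0410
TF0411
TF0412
TF0413
TF0414
TF0415
TF0416
TF0417
TF0418
TF0419
TF0420
TF0421
TF0422
TF0423
TF0424
TF0425
TF0426
TF0427
TF0428
TF0429
TF0430
TF0431
TF0432
TF0433
TF0434
TF0435
TF0436
TF0437
TF0438
TF0439
TF0440
TF0441
TF0442
TF0443
TF0444
TF0445
TF0446
TF0447
TF0448
TF0449
TF0450
TF0451
TF0452
TF0453
TF0454
TF0455
TF0456
TF0457
TF0458
TF0459
TF0460
TF0461
TF0462
TF0463
TF0464
TF0465
TF0466
TF0467
TF0468
TF0469
TF0470
TF0471
TF0472
TF0473
TF0474
TF0475
TF0476
TF0477
TF0478
TF0479
TF0480
TF0481
TF0482
TF0483
TF0484
TF0485
TF0486
TF0487
TF0488
TF0489
TF0490
TF0491
TF0492
TF0493
TF0494
TF0495
TF0496
TF0497
TF0498
TF0499
TF0500
TF0501
TF0502
TF0503
TF0504
TF0505
TF0506
TF0507
TF0508
TF0509
TF0510
TF0511
TF0512
TF0513
TF0514
TF0515
TF0516
TF0517
TF0518
TF0519
TF0520
TF0521
TF0522
TF0523
TF0524
TF0525
TF0526
TF0527
TF0528
TF0529
TF0530
TF0531
TF0532
TF0533
TF0534
TF0535
TF0536
TF0537
TF0538
TF0539
TF0540
TF0541
TF0542
TF0543
TF0544
TF0545
TF0546
TF0547
TF0548
TF0549
TF0550
TF0551
TF0552
TF0553
TF0554
TF0555
TF0556
TF0557
TF0558
TF0559
TF0560
TF0561
TF0562
TF0563
TF0564
TF0565
TF0566
TF0567
TF0568
TF0569
TF0570
TF0571
TF0572
TF0573
TF0574
TF0575
TF0576
TF0577
TF0578
TF0579
TF0580
TF0581
TF0582
TF0583
TF0584
TF0585
TF0586
TF0587
TF0588
TF0589
TF0590
TF0591
TF0592
TF0593
TF0594
TF0595
TF0596
TF0597
TF0598
TF0599
TF0600
TF0601
TF0602
TF0603
TF0604
TF0605
TF0606
TF0607
TF0608
TF0609
TF0610
TF0611
TF0612
TF0613
TF0614
TF0615
TF0616
TF0617
TF0618
TF0619
TF0620
TF0621
TF0622
TF0623
TF0624
TF0625
TF0626
TF0627
TF0628
TF0629
TF0630
TF0631
TF0632
TF0633
TF0634
TF0635
TF0636
TF0637
TF0638
TF0639
TF0640
TF0641
TF0642
TF0643
TF0644
TF0645
TF0646
TF0647
TF0648
TF0649
TF0650
TF0651
TF0652
TF0653
TF0654
TF0655
TF0656
TF0657
TF0658
TF0659
TF0660
TF0661
TF0662
TF0663
TF0664
TF0665
TF0666
TF0667
TF0668
TF0669
TF0670
TF0671
TF0672
TF0673
TF0674
TF0675
TF0676
TF0677
TF0678
TF0679
TF0680
TF0681
TF0682
TF0683
TF0684
TF0685
TF0686
TF0687
TF0688
TF0689
TF0690
TF0691
TF0692
TF0693
TF0694
TF0695
TF0696
TF0697
TF0698
TF0699
TF0700
TF0701
TF0702
TF0703
TF0704
TF0705
TF0706
TF0707
TF0708
TF0709
TF0710
TF0711
TF0712
TF0713
TF0714
TF0715
TF0716
TF0717
TF0718
TF0719
TF0720
TF0721
TF0722
TF0723
TF0724
TF0725
TF0726
TF0727
TF0728
TF0729
TF0730
TF0731
TF0732
TF0733
TF0734
TF0735
TF0736
TF0737
TF0738
TF0739
TF0740
TF0741
TF0742
TF0743
TF0744
TF0745
TF0746
TF0747
TF0748
TF0749
TF0750
TF0751
TF0752
TF0753
TF0754
TF0755
TF0756
TF0757
TF0758
TF0759
TF0760
TF0761
TF0762
TF0763
TF0764
TF0765
TF0766
TF0767
TF0768
TF0769
TF0770
TF0771
TF0772
TF0773
TF0774
TF0775
TF0776
TF0777
TF0778
TF0779
TF0780
TF0781
TF0782
TF0783
TF0784
TF0785
TF0786
TF0787
TF0788
TF0789
TF0790
TF0791
TF0792
TF0793
TF0794
TF0795
TF0796
TF0797
TF0798
TF0799
TF0800
TF0801
TF0802
TF0803
TF0804
TF0805
TF0806
TF0807
TF0808
TF0809
TF0810
TF0811
TF0812
TF0813
TF0814
TF0815
TF0816
TF0817
TF0818
TF0819
TF0820
TF0821
TF0822
TF0823
TF0824
TF0825
TF0826
TF0827
TF0828
TF0829
TF0830
TF0831
TF0832
TF0833
TF0834
TF0835
TF0836
TF0837
TF0838
TF0839
TF0840
TF0841
TF0842
TF0843
TF0844
TF0845
TF0846
TF0847
TF0848
TF0849
TF0850
TF0851
TF0852
TF0853
TF0854
TF0855
TF0856
TF0857
TF0858
TF0859
TF0860
TF0861
TF0862
TF0863
TF0864
TF0865
TF0866
TF0867
TF0868
TF0869
TF0870
TF0871
TF0872
TF0873
TF0874
TF0875
TF0876
TF0877
TF0878
TF0879
TF0880
TF0881
TF0882
TF0883
TF0884
TF0885
TF0886
TF0887
TF0888
TF0889
TF0890
TF0891
TF0892
TF0893
TF0894
TF0895
TF0896
TF0897
TF0898
TF0899
TF0900
TF0901
TF0902
TF0903
TF0904
TF0905
TF0906
TF0907
TF0908
TF0909
TF0910
TF0911
TF0912
TF0913
TF0914
TF0915
TF0916
TF0917
TF0918
TF0919
TF0920
TF0921
TF0922
TF0923
TF0924
TF0925
TF0926
TF0927
TF0928
TF0929
TF0930
TF0931
TF0932
TF0933
TF0934
TF0935
TF0936
TF0937
TF0938
TF0939
TF0940
TF0941
TF0942
TF0943
TF0944
TF0945
TF0946
TF0947
TF0948
TF0949
TF0950
TF0951
TF0952
TF0953
TF0954
TF0955
TF0956
TF0957
TF0958
TF0959
TF0960
TF0961
TF0962
TF0963
TF0964
TF0965
TF0966
TF0967
TF0968
TF0969
TF0970
TF0971
TF0972
TF0973
TF0974
TF0975
TF0976
TF0977
TF0978
TF0979
TF0980
TF0981
TF0982
TF0983
TF0984
TF0985
TF0986
TF0987
TF0988
TF0989
TF0990
TF0991
TF0992
TF0993
TF0994
TF0995
TF0996
TF0997
TF0998
TF0999
TF1000
TF1001
TF1002
TF1003
TF1004
TF1005
TF1006
TF1007
TF1008
TF1009
TF1010
TF1011
TF1012
TF1013
TF1014
TF1015
TF1016
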