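wavelength_nm,relative_power
380,1.09151891
381,1.09386744
382,1.09616692
383,1.09841697
384,1.10061710
385,1.10276677
386,1.10486532
387,1.10691199
388,1.10890586
389,1.11084587
390,1.11273075
391,1.11455900
392,1.11632888
393,1.11803831
394,1.11968486
395,1.12126568
396,1.12277744
397,1.12421625
398,1.12557759
399,1.12685626
400,1.12804627
401,1.12914080
402,1.13013214
403,1.13101162
404,1.13176963
405,1.13239558
406,1.13287799
407,1.13320456
408,1.13336229
409,1.13333772
410,1.13311719
411,1.13268714
412,1.13203457
413,1.13114748
414,1.13001540
415,1.12862999
416,1.12698563
417,1.12508006
418,1.12291499
419,1.12049665
420,1.11783626
421,1.11495047
422,1.11186154
423,1.10859746
424,1.10519179
425,1.10168337
426,1.09811578
427,1.09453655
428,1.09099623
429,1.08754725
430,1.08424266
431,1.08113471
432,1.07827348
433,1.07570543
434,1.07347207
435,1.07160877
436,1.07014370
437,1.06909703
438,1.06831251
439,1.06762906
440,1.06705260
441,1.06658805
442,1.06623927
443,1.06598118
444,1.06578798
445,1.06566149
446,1.06560323
447,1.06561446
448,1.06569614
449,1.06584895
450,1.06607326
451,1.06636913
452,1.06673631
453,1.06717427
454,1.06768213
455,1.06825873
456,1.06890262
457,1.06961202
458,1.07038488
459,1.07121886
460,1.07216708
461,1.07328125
462,1.07455491
463,1.07597925
464,1.07754327
465,1.07923398
466,1.08103670
467,1.08293533
468,1.08491269
469,1.08695084
470,1.08903149
471,1.09113627
472,1.09324711
473,1.09534651
474,1.09741784
475,1.09944555
476,1.10141535
477,1.10331441
478,1.10513140
479,1.10685658
480,1.10848178
481,1.11000043
482,1.11140745
483,1.11269918
484,1.11387327
485,1.11492856
486,1.11586491
487,1.11668311
488,1.11738468
489,1.11797176
490,1.11844696
491,1.11881325
492,1.11907384
493,1.11923209
494,1.11929141
495,1.11925521
496,1.11912682
497,1.11890950
498,1.11860635
499,1.11822031
500,1.11775416
501,1.11721054
502,1.11659342
503,1.11590731
504,1.11515431
505,1.11433636
506,1.11345520
507,1.11251245
508,1.11150960
509,1.11044802
510,1.10932900
511,1.10815372
512,1.10692332
513,1.10563886
514,1.10430135
515,1.10291178
516,1.10147108
517,1.09998015
518,1.09843990
519,1.09685117
520,1.09521482
521,1.09353168
522,1.09180257
523,1.09002829
524,1.08820965
525,1.08634743
526,1.08444241
527,1.08249536
528,1.08050706
529,1.07847826
530,1.07640974
531,1.07430223
532,1.07215651
533,1.06997332
534,1.06775344
535,1.06549763
536,1.06320666
537,1.06088130
538,1.05852236
539,1.05613063
540,1.05370694
541,1.05125211
542,1.04876701
543,1.04625251
544,1.04370951
545,1.04113894
546,1.03854174
547,1.03591892
548,1.03327147
549,1.03060044
550,1.02790693
551,1.02519205
552,1.02245696
553,1.01970284
554,1.01693094
555,1.01414253
556,1.01133891
557,1.00852144
558,1.00569151
559,1.00285054
560,1.00000000
561,0.99714139
562,0.99427624
563,0.99140613
564,0.98853264
565,0.98565741
566,0.98278208
567,0.97990834
568,0.97703788
569,0.97417240
570,0.97131363
571,0.96846331
572,0.96562317
573,0.96279495
574,0.95998039
575,0.95718122
576,0.95439915
577,0.95163589
578,0.94889311
579,0.94617247
580,0.94347559
581,0.94080406
582,0.93815943
583,0.93554320
584,0.93295682
585,0.93040171
586,0.92787920
587,0.92539057
588,0.92293705
589,0.92051978
590,0.91813983
591,0.91579821
592,0.91349583
593,0.91123352
594,0.90901205
595,0.90683206
596,0.90469414
597,0.90259876
598,0.90054632
599,0.89853711
600,0.89657178
601,0.89466533
602,0.89282491
603,0.89105023
604,0.88934080
605,0.88769592
606,0.88611467
607,0.88459596
608,0.88313849
609,0.88174077
610,0.88040115
611,0.87911779
612,0.87788871
613,0.87671177
614,0.87558469
615,0.87450507
616,0.87347041
617,0.87247807
618,0.87152535
619,0.87060947
620,0.86972758
621,0.86887679
622,0.86805415
623,0.86725672
624,0.86648153
625,0.86572561
626,0.86498601
627,0.86425981
628,0.86354412
629,0.86283610
630,0.86213297
631,0.86143204
632,0.86073066
633,0.86002630
634,0.85931651
635,0.85859894
636,0.85787136
637,0.85713165
638,0.85637780
639,0.85560794
640,0.85482030
641,0.85401326
642,0.85318532
643,0.85233511
644,0.85146140
645,0.85056308
646,0.84963918
647,0.84868885
648,0.84771136
649,0.84670611
650,0.84567263
651,0.84461053
652,0.84351957
653,0.84239960
654,0.84125057
655,0.84007253
656,0.83886561
657,0.83763005
658,0.83636616
659,0.83507430
660,0.83375494
661,0.83240858
662,0.83103580
663,0.82963721
664,0.82821348
665,0.82676533
666,0.82529349
667,0.82379873
668,0.82228186
669,0.82074369
670,0.81918506
671,0.81760681
672,0.81600979
673,0.81439486
674,0.81276288
675,0.81111469
676,0.80945115
677,0.80777308
678,0.80608132
679,0.80437667
680,0.80265992
681,0.80093185
682,0.79919323
683,0.79744477
684,0.79568720
685,0.79392121
686,0.79214746
687,0.79036659
688,0.78857922
689,0.78678594
690,0.78498732
691,0.78318390
692,0.78137620
693,0.77956470
694,0.77774988
695,0.77593218
696,0.77411202
697,0.77228980
698,0.77046590
699,0.76864066
700,0.76681442
701,0.76498749
702,0.76316018
703,0.76133275
704,0.75950546
705,0.75767856
706,0.75585227
707,0.75402680
708,0.75220235
709,0.75037910
710,0.74855721
711,0.74673686
712,0.74491818
713,0.74310131
714,0.74128638
715,0.73947350
716,0.73766278
717,0.73585432
718,0.73404822
719,0.73224455
720,0.73044340
721,0.72864483
722,0.72684893
723,0.72505574
724,0.72326532
725,0.72147774
726,0.71969303
727,0.71791124
728,0.71613241
729,0.71435659
730,0.71258380
731,0.71081409
732,0.70904747
733,0.70728398
734,0.70552365
735,0.70376650
736,0.70201255
737,0.70026183
738,0.69851434
739,0.69677012
740,0.69502918
741,0.69329154
742,0.69155720
743,0.68982620
744,0.68809853
745,0.68637421
746,0.68465326
747,0.68293568
748,0.68122149
749,0.67951069
750,0.67780330
751,0.67609933
752,0.67439878
753,0.67270167
754,0.67100799
755,0.66931777
756,0.66763100
757,0.66594770
758,0.66426786
759,0.66259151
760,0.66091864
761,0.65924925
762,0.65758337
763,0.65592098
764,0.65426210
765,0.65260673
766,0.65095488
767,0.64930655
768,0.64766174
769,0.64602046
770,0.64438272
771,0.64274852
772,0.64111785
773,0.63949073
774,0.63786716
775,0.63624715
776,0.63463068
777,0.63301778
778,0.63140843
779,0.62980265
780,0.62820043
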