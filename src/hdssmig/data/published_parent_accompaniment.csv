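life_stage,length,sex,category,n,pct
child,short,female,neither,323,5.9
child,short,female,mother_only,2652,48.7
child,short,female,father_only,121,2.2
child,short,female,both,2350,43.2
child,short,male,neither,454,7.4
child,short,male,mother_only,2831,46.0
child,short,male,father_only,223,3.6
child,short,male,both,2653,43.1
child,long,female,neither,816,8.7
child,long,female,mother_only,4145,44.3
child,long,female,father_only,262,2.8
child,long,female,both,4133,44.2
child,long,male,neither,997,9.4
child,long,male,mother_only,4368,41.2
child,long,male,father_only,401,3.8
child,long,male,both,4836,45.6
adolescent,short,female,neither,1947,69.3
adolescent,short,female,mother_only,469,16.7
adolescent,short,female,father_only,80,2.8
adolescent,short,female,both,315,11.2
adolescent,short,male,neither,1425,76.7
adolescent,short,male,mother_only,217,11.7
adolescent,short,male,father_only,62,3.3
adolescent,short,male,both,153,8.2
adolescent,long,female,neither,3914,73.8
adolescent,long,female,mother_only,534,10.1
adolescent,long,female,father_only,141,2.7
adolescent,long,female,both,716,13.5
adolescent,long,male,neither,2636,78.1
adolescent,long,male,mother_only,222,6.6
adolescent,long,male,father_only,111,3.3
adolescent,long,male,both,404,12.0
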