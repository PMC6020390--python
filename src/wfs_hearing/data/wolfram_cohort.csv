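patient_id,sex,enrollment_age,sibship,dm_onset,di_onset,hl_onset,oa_onset,cochlear_implant,n_sessions
WFS_01,M,12.9,,3.5,9.0,9.0,5.0,0,1
WFS_02,F,10.9,,6.2,9.7,Normal,9.5,0,6
WFS_03,M,17.9,,4.6,6.0,6.0,6.0,0,6
WFS_04,F,23.7,,2.2,12.3,5.0,12.3,0,6
WFS_05,F,13.7,,3.9,No dx,1.7,12.6,1,0
WFS_07,M,7.3,,2.7,7.3,11.2,7.0,0,5
WFS_09,M,14.4,S1,10.8,14.7,Normal,10.9,0,3
WFS_10,F,11.6,S1,7.0,11.0,Normal,8.0,0,5
WFS_11,M,8.3,S1,7.8,10.0,Normal,6.0,0,3
WFS_12,M,22.9,,6.3,17.0,7.0,17.0,0,6
WFS_13,F,5.4,,4.7,7.0,7.4,5.2,0,6
WFS_14,F,12.6,,6.2,11.2,9.1,7.9,0,4
WFS_15,F,10.9,,2.7,12.0,9.0,7.0,0,4
WFS_16,F,25.8,,13.0,14.5,25.8,13.0,0,5
WFS_17,F,17.1,S2,4.9,Not Diagnosed,16.3,15.3,0,5
WFS_18,M,12.0,,5.1,10.3,11.9,10.1,0,4
WFS_19,F,11.9,,Not Diagnosed,Not Diagnosed,3.0,5.7,1,0
WFS_22,M,15.7,,13.9,Not Diagnosed,Normal,13.0,0,4
WFS_23,F,17.7,S3,5.0,Not Diagnosed,10.0,17.0,0,3
WFS_24,F,16.3,S3,4.0,5.5,8.5,14.0,0,3
WFS_25,F,7.9,S3,4.0,Not Diagnosed,7.9,7.0,0,2
WFS_27,M,10.1,,3.8,8.9,10.1,8.0,0,3
WFS_28,M,6.9,,3.8,Not Diagnosed,Normal,3.8,0,3
WFS_29,F,5.1,S2,Not Diagnosed,Not Diagnosed,3.0,Not Diagnosed,0,2
WFS_30,F,22.7,,6.9,22.4,Normal,19.6,0,2
WFS_31,F,10.8,,4.5,Not Diagnosed,8.8,7.0,0,2
WFS_32,F,7.6,,Not Diagnosed,Not Diagnosed,0.4,6.4,1,0
WFS_33,M,6.3,,4.8,6.2,6.3,6.0,0,2
WFS_34,F,14.0,S4,3.5,13.0,3.0,Not Diagnosed,0,1
WFS_35,F,17.1,S4,3.5,6.2,6.0,13.0,0,2
WFS_36,F,11.1,,7.0,10.1,6.1,10.0,0,1
WFS_37,F,21.8,,6.0,17.0,16.0,18.0,0,1
WFS_38,M,12.9,,Not Diagnosed,Not Diagnosed,2.8,10.9,1,0
WFS_39,M,13.0,,3.0,Not Diagnosed,13.0,9.0,0,1
WFS_40,F,17.1,,13.0,13.5,Normal,8.0,0,1
WFS_42,M,8.3,,5.0,No dx,6.4,7.4,0,1
WFS_43,M,21.1,,5.0,16.0,Normal,14.0,0,1
WFS_44,M,10.9,,5.0,Not Diagnosed,7.0,9.0,0,1
WFS_45,M,6.0,,4.0,Not Diagnosed,Normal,Not Diagnosed,0,1
WFS_46,M,21.2,,5.0,Not Diagnosed,12.0,11.0,0,1
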