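name,shifts,range_high,range_low
Nicotinamide ribotide,9.59;9.33;8.99,9.595,9.581
NAD+,9.32;9.13;8.82;8.42;6.08,9.146,9.128
NADP+,9.28;9.09;8.82;8.40;8.13,8.832,8.810
AMP,8.60;8.25;6.13,8.609,8.584
Glucose,5.21,5.213,5.207
Maltose,5.40;5.22,5.406,5.398
Mannose,5.17,5.174,5.169
Galactoside,4.46;4.18;3.93;3.76;3.61,4.456,4.448
Fatty acid,5.31;1.28;0.89,5.325,5.288
3-Hydroxykynurenine,7.44;6.89;6.69,6.704,6.677
Acetate,1.93,1.933,1.930
Alanine,1.47,1.474,1.460
beta-Alanine,3.16;3.54,2.552,2.530
Arginine,1.91;1.73,1.742,1.723
Asparagine,2.93;2.83,2.930,2.916
Aspartate,2.80;2.65,2.796,2.785
Glutamate,2.34;2.12;2.05,2.360,2.320
Glutamine,2.44;2.12,2.460,2.420
Histidine,7.78;7.05,7.055,7.043
Hydroxyisovalerate,2.34;1.24,1.248,1.239
Isoleucine,1.00;0.92,1.007,0.989
Lactate,4.10;1.31,1.321,1.306
Leucine,1.73;0.95,0.962,0.930
Methionine sulfoxide,3.88;3.01;2.74;2.32,2.739,2.734
Phenylalanine,7.41;7.31,7.424,7.401
Phosphocholine,4.15;3.58;3.21,4.163,4.138
Proline,2.12;2.01,2.039,1.995
Tryptophan,7.72;7.52;7.31,7.729,7.711
Tyrosine,7.18;6.89,7.194,7.169
Valine,1.03;0.98,0.987,0.970
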