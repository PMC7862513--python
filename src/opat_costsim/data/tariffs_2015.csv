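drg_code,ugvd,ugvd_br,mvd,inlier_br,ogvd,ogvd_br
I01Z,11,0.326,33.0,6.033,50,0.076
I03B,6,0.346,18.5,3.729,33,0.079
I04Z,5,0.318,16.2,3.544,28,0.075
I12A,7,0.354,21.6,3.484,39,0.080
I12B,5,0.314,15.5,2.302,30,0.071
I12C,3,0.293,9.2,1.391,19,0.067
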