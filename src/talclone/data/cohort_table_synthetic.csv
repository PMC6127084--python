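sample_id,STIL_TAL1,CDKN2A_9p,PTEN_cn,PTEN_exon7,NOTCH1,FBXW7,IL7R,del_6q
6030,mutation,loss,wt,mutation,wt,wt,wt,wt
6116,mutation,loss,wt,wt,mutation,wt,wt,wt
CUL76,mutation,loss,loss,wt,mutation,wt,wt,wt
CF5,mutation,loss,wt,mutation,wt,wt,wt,wt
CF6,mutation,loss,wt,wt,wt,mutation,wt,loss
CF10,mutation,loss,wt,mutation,wt,wt,wt,wt
HK328,mutation,loss,loss,wt,wt,wt,wt,loss
BR74,mutation,loss,loss,wt,wt,wt,wt,loss
BR75,mutation,loss,wt,wt,wt,wt,wt,wt
S1,mutation,loss,wt,mutation,wt,wt,wt,wt
S2,mutation,loss,loss,wt,mutation,wt,wt,wt
RPMI-8402,mutation,loss,wt,wt,wt,wt,wt,wt
CF2,mutation,loss,wt,wt,mutation,wt,wt,wt
CF7,mutation,wt,wt,wt,wt,wt,wt,wt
CF13,mutation,loss,wt,wt,wt,wt,wt,loss
HK101,mutation,loss,wt,wt,wt,wt,mutation,loss
HK146,mutation,loss,wt,wt,mutation,wt,wt,wt
HK211,mutation,loss,wt,wt,wt,wt,wt,wt
T041,mutation,loss,wt,wt,wt,mutation,wt,loss
T187,mutation,loss,wt,wt,wt,wt,wt,wt
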