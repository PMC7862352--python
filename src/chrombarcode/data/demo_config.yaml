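# Bundled demo configuration: simulate a small banded genome and run every
# pipeline stage.  Override any key on the command line or in a copy.
seed: 7
simulate: true
n_chrom: 1
chrom_length: 12000000
cell_type: LCL
depth: 150000
marks: H3K9ac,H3K4me3,H3K27me3
phases: G1,G2M
window: 5000
step: 5000
pixel: 1500000
w_list: 500,1000,2000,5000,10000,20000,50000,200000,1000000
titrate: 1.0,0.1
tail_fraction: 0.03
p_threshold: 0.05
pseudocount: 1.0
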