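# Homolog-retrieval funnel: 36,526 query proteins, 16,636 with fewer than
# three hits at E < 1e-2 (excluded), 19,890 retained.
n_retained: 19890
n_excluded: 16636
e_max: 1.0e-2
min_hits: 3
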