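# Example high-LD exclusion regions (0-based half-open BED).
# Replace with a real catalogue for production use.
1	48000000	52000000
2	86000000	101000000
2	183000000	190000000
3	47500000	50000000
5	44500000	50500000
6	25000000	33500000
8	8000000	12000000
11	45000000	57000000
17	40000000	43000000
20	32000000	34500000
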