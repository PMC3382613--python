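# Published per-cluster timestep counts for the dominant tubulin
# conformations of the 5 ns trajectory (251 snapshots total). Used as the
# reference input for the persistence worked example and rank checks.
conformation	timesteps
1	13
2	2
3	29
4	9
5	57
6	32
7	69
8	4
9	13
10	19
11	4
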