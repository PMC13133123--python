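# Standardized codec parameter sets for code rates of 0.50, 1.00 and
# 1.50 bit/nt at a design length of 152 nt (38 bytes at 2 bit/nt).
#
# rs: inner RS(38, inner_k) per sequence (index + payload chunk + parity);
#     outer RS(outer_n, outer_k) column-wise across the sequences of a block.
#     The inner/outer redundancy split at each rate is a recorded free choice.
# fountain: droplets = seed + XOR of source segments (robust soliton, c/delta)
#     + detection-only RS parity; droplet count = ceil(K * (1 + overhead)).
rs:
  "0.50": {length: 152, index_bytes: 2, inner_k: 26, outer_n: 48, outer_k: 19}
  "1.00": {length: 152, index_bytes: 2, inner_k: 30, outer_n: 28, outer_k: 19}
  "1.50": {length: 152, index_bytes: 2, inner_k: 34, outer_n: 64, outer_k: 57}
fountain:
  "0.50": {length: 152, seed_bytes: 4, parity_bytes: 4, overhead: 2.158, c: 0.03, delta: 0.05}
  "1.00": {length: 152, seed_bytes: 4, parity_bytes: 4, overhead: 0.579, c: 0.03, delta: 0.05}
  "1.50": {length: 152, seed_bytes: 4, parity_bytes: 4, overhead: 0.053, c: 0.03, delta: 0.05}
baseline:
  "max": {length: 152, index_bytes: 2}
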