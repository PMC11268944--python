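# ALS Functional Rating Scale - Revised: 12 items rated 0-4, total 0-48
# (higher = better function).
instrument: alsfrs_r
n_items: 12
item_min: 0
item_max: 4
subscales:
  - name: total
    transform: sum
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
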