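# Multiple Sclerosis Impact Scale (original version): 29 items rated 1-5.
# Physical impact = items 1-20, psychological impact = items 21-29, each
# rescaled to 0-100: 100 * (sum - n) / (4 * n).
instrument: msis29
n_items: 29
item_min: 1
item_max: 5
subscales:
  - name: physical
    transform: scaled_0_100
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  - name: psychological
    transform: scaled_0_100
    items: [21, 22, 23, 24, 25, 26, 27, 28, 29]
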