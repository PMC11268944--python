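# Generic 9-item fatigue severity scale (1-7 per item), raw total 9-63.
instrument: fatigue
n_items: 9
item_min: 1
item_max: 7
subscales:
  - name: total
    transform: sum
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9]
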