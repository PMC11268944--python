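# Generic 10-item mood scale (0-4 per item), scored 0-100.
instrument: mood
n_items: 10
item_min: 0
item_max: 4
subscales:
  - name: total
    transform: scaled_0_100
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
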