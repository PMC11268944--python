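# Generic 5-item quality-of-life scale (1-5 per item), scored 0-100.
instrument: qol
n_items: 5
item_min: 1
item_max: 5
subscales:
  - name: total
    transform: scaled_0_100
    items: [1, 2, 3, 4, 5]
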