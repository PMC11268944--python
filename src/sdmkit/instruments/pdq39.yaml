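# Parkinson's Disease Questionnaire: 39 items rated 0-4; eight dimension
# scores 100 * sum / (4 * n_items); summary index = mean of the eight
# dimension scores.
instrument: pdq39
n_items: 39
item_min: 0
item_max: 4
summary: mean_of_subscales
summary_name: summary_index
subscales:
  - name: mobility
    transform: scaled_0_100
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  - name: adl
    transform: scaled_0_100
    items: [11, 12, 13, 14, 15, 16]
  - name: emotional
    transform: scaled_0_100
    items: [17, 18, 19, 20, 21, 22]
  - name: stigma
    transform: scaled_0_100
    items: [23, 24, 25, 26]
  - name: social
    transform: scaled_0_100
    items: [27, 28, 29]
  - name: cognition
    transform: scaled_0_100
    items: [30, 31, 32, 33]
  - name: communication
    transform: scaled_0_100
    items: [34, 35, 36]
  - name: bodily_discomfort
    transform: scaled_0_100
    items: [37, 38, 39]
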