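{
  "fields": {
    "wt_b1_t1": {
      "classified": 25,
      "farred_spots": 25,
      "green_spots": 25,
      "orphaned": 0,
      "pairs": 25,
      "rejected_by_filter": 0,
      "retained": 25
    },
    "wt_b1_t2": {
      "classified": 25,
      "farred_spots": 25,
      "green_spots": 25,
      "orphaned": 0,
      "pairs": 25,
      "rejected_by_filter": 1,
      "retained": 24
    },
    "wt_b2_t1": {
      "classified": 25,
      "farred_spots": 25,
      "green_spots": 25,
      "orphaned": 0,
      "pairs": 25,
      "rejected_by_filter": 1,
      "retained": 24
    },
    "wt_b2_t2": {
      "classified": 25,
      "farred_spots": 25,
      "green_spots": 25,
      "orphaned": 0,
      "pairs": 25,
      "rejected_by_filter": 2,
      "retained": 23
    }
  },
  "seed": 7,
  "totals": {
    "classified": 100,
    "complexes": 100,
    "farred_spots": 100,
    "green_spots": 100,
    "orphaned": 0,
    "pairs": 100,
    "rejected_by_filter": 4,
    "retained": 96,
    "traces_flagged": 0
  }
}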