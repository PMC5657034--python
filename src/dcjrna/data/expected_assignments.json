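{
  "trna_pair": {
    "epsilon": 0.5,
    "matches": [[3, 3], [5, 4], [2, 2]],
    "deleted": [1, 4],
    "inserted": [1],
    "desired_row": [6, 2, 3, 5],
    "deleted_row": [1, 4],
    "inserted_row": [6],
    "n_operations": 2
  },
  "small_pair": {
    "epsilon": 0.6,
    "matches": [[1, 1], [3, 4], [2, 2]],
    "deleted": [],
    "inserted": [3],
    "desired_row": [1, 2, 6, 3],
    "deleted_row": [],
    "inserted_row": [6],
    "n_operations": 2
  },
  "medium_pair": {
    "epsilon": 0.6,
    "matches": [[7, 6], [6, 5], [4, 3], [3, 2], [5, 1]],
    "deleted": [1, 2],
    "inserted": [4],
    "desired_row": [5, 3, 4, 11, 6, 7],
    "deleted_row": [1, 2],
    "inserted_row": [11]
  },
  "large_pair": {
    "epsilon": 0.6,
    "matches": [[2, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 8], [8, 9], [9, 10], [10, 11], [11, 12], [1, 2]],
    "deleted": [],
    "inserted": [1],
    "desired_row": [12, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
    "deleted_row": [],
    "inserted_row": [12],
    "n_operations": 1
  }
}
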