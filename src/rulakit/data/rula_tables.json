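{
  "version": 1,
  "description": "Standard RULA lookup tables (upper-limb Table A, neck/trunk/legs Table B, grand-score Table C) transcribed from the published worksheet. Indexing is 1-based sub-scores; table_a[upper-1][lower-1][wrist-1][twist-1], table_b[neck-1][trunk-1][legs-1], table_c[scoreA-1][scoreB-1] with scores above the last row/column clamped to it.",
  "table_a": [
    [
      [[1, 2], [2, 2], [2, 3], [3, 3]],
      [[2, 2], [2, 2], [3, 3], [3, 3]],
      [[2, 3], [3, 3], [3, 3], [4, 4]]
    ],
    [
      [[2, 3], [3, 3], [3, 4], [4, 4]],
      [[3, 3], [3, 3], [3, 4], [4, 4]],
      [[3, 4], [4, 4], [4, 4], [5, 5]]
    ],
    [
      [[3, 3], [4, 4], [4, 4], [5, 5]],
      [[3, 4], [4, 4], [4, 4], [5, 5]],
      [[4, 4], [4, 4], [4, 5], [5, 5]]
    ],
    [
      [[4, 4], [4, 4], [4, 5], [5, 5]],
      [[4, 4], [4, 4], [4, 5], [5, 5]],
      [[4, 4], [4, 5], [5, 5], [6, 6]]
    ],
    [
      [[5, 5], [5, 5], [5, 6], [6, 7]],
      [[5, 6], [6, 6], [6, 7], [7, 7]],
      [[6, 6], [6, 7], [7, 7], [7, 8]]
    ],
    [
      [[7, 7], [7, 7], [7, 8], [8, 9]],
      [[8, 8], [8, 8], [8, 9], [9, 9]],
      [[9, 9], [9, 9], [9, 9], [9, 9]]
    ]
  ],
  "table_b": [
    [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],
    [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],
    [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],
    [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],
    [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],
    [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]]
  ],
  "table_c": [
    [1, 2, 3, 3, 4, 5, 5],
    [2, 2, 3, 4, 4, 5, 5],
    [3, 3, 3, 4, 4, 5, 6],
    [3, 3, 3, 4, 5, 6, 6],
    [4, 4, 4, 5, 6, 7, 7],
    [4, 4, 5, 6, 6, 7, 7],
    [5, 5, 6, 6, 7, 7, 7],
    [5, 5, 6, 7, 7, 7, 7]
  ]
}
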