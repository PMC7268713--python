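{
  "factor_n": [19, 25, 16, 6, 4],
  "mean_age": [55, 43, 34, 52, 30],
  "blocks": {
    "gender": {
      "Male": [7, 8, 10, 6, 3],
      "Female": [12, 17, 6, 0, 1]
    },
    "age": {
      "< 40": [4, 13, 12, 1, 3],
      "40-60": [7, 4, 3, 3, 1],
      "60+": [8, 8, 1, 2, 0]
    },
    "education": {
      "Under high school": [3, 6, 3, 1, 0],
      "High school": [4, 1, 2, 1, 0],
      "Secondary specialised": [3, 1, 1, 3, 1],
      "College": [3, 4, 2, 1, 1],
      "University": [6, 13, 8, 0, 2]
    },
    "eq5d_profile": {
      "11111": [8, 7, 8, 4, 0],
      "11112": [2, 3, 2, 0, 0],
      "11121": [3, 5, 1, 0, 1],
      "11122": [1, 3, 2, 2, 1],
      "Other": [5, 6, 3, 0, 2]
    },
    "vas": {
      "80-100": [10, 17, 9, 3, 3],
      "60-80": [8, 4, 7, 3, 1],
      "< 60": [1, 3, 0, 0, 0]
    },
    "residence": {
      "City": [12, 13, 10, 2, 3],
      "Non-city": [7, 12, 6, 4, 1]
    },
    "region": {
      "Southwest China": [13, 12, 4, 3, 1],
      "East China": [5, 4, 7, 3, 2],
      "North China": [0, 5, 4, 0, 1],
      "Other": [1, 4, 1, 0, 0]
    }
  },
  "notes": {
    "eq5d_profile": "factor 2 column sums to 24 of 25 exemplars; one exemplar did not complete the EQ-5D questionnaire",
    "vas": "factor 2 column sums to 24 of 25 exemplars; same non-response"
  }
}
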