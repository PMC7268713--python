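{
  "total": 110,
  "blocks": {
    "gender": {"Male": 57, "Female": 53},
    "age": {"< 40": 44, "40-60": 35, "60+": 31},
    "education": {
      "Under high school": 20,
      "High school": 14,
      "Secondary specialised": 15,
      "College": 18,
      "University": 42
    },
    "eq5d_profile": {"11111": 42, "11112": 15, "11121": 16, "11122": 14, "Other": 22},
    "vas": {"80-100": 69, "60-80": 35, "< 60": 5},
    "residence": {"City": 63, "Non-city": 47},
    "region": {"Southwest China": 54, "East China": 34, "North China": 13, "Other": 9}
  },
  "notes": {
    "eq5d_profile": "one participant did not complete the EQ-5D questionnaire; block sums to 109",
    "vas": "same non-response as eq5d_profile; block sums to 109"
  }
}
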