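{
  "description": "Marginal totals after the first 20 patients of the fracture-trial worked example: two treatment groups (A, B) and four prognostic factors, plus the profile of the 21st patient awaiting allocation.",
  "arms": ["A", "B"],
  "factors": [
    {
      "name": "Gender",
      "categories": ["Male", "Female"],
      "counts": [[3, 2], [7, 8]]
    },
    {
      "name": "Age band",
      "categories": ["<80", ">=80"],
      "counts": [[6, 9], [4, 1]]
    },
    {
      "name": "Type of fracture",
      "categories": ["Proximal femur", "Distal forearm", "Clinical vertebral", "Other"],
      "counts": [[0, 2], [4, 4], [0, 0], [6, 4]]
    },
    {
      "name": "Time since fracture",
      "categories": ["0 to 3 months", ">3 months"],
      "counts": [[5, 7], [5, 3]]
    }
  ],
  "next_patient": {
    "levels": [1, 0, 0, 0],
    "profile": ["Female", "<80", "Proximal femur", "0 to 3 months"]
  }
}
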