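{
  "name": "naranjo-1981",
  "description": "Default weight matrix for the 10-item Naranjo ADR probability questionnaire, with the original score-to-category boundaries. The lowest category ('doubtful' in the 1981 wording) is relabelled 'unlikely' to match the shared four-point causality scale.",
  "questions": {
    "Q1": "Are there previous conclusive reports on this reaction?",
    "Q2": "Did the adverse event appear after the suspected drug was administered?",
    "Q3": "Did the adverse reaction improve when the drug was discontinued or a specific antagonist was administered?",
    "Q4": "Did the adverse reaction reappear after the drug was readministered?",
    "Q5": "Are there alternative causes (other than the drug) that could on their own have caused the reaction?",
    "Q6": "Did the reaction reappear when a placebo was given?",
    "Q7": "Was the drug detected in the blood (or other fluids) in concentrations known to be toxic?",
    "Q8": "Was the reaction more severe when the dose was increased, or less severe when the dose was decreased?",
    "Q9": "Did the patient have a similar reaction to the same or similar drugs in any previous exposure?",
    "Q10": "Was the adverse event confirmed by any objective evidence?"
  },
  "weights": {
    "Q1": {"yes": 1, "no": 0, "unknown": 0},
    "Q2": {"yes": 2, "no": -1, "unknown": 0},
    "Q3": {"yes": 1, "no": 0, "unknown": 0},
    "Q4": {"yes": 2, "no": -1, "unknown": 0},
    "Q5": {"yes": -1, "no": 2, "unknown": 0},
    "Q6": {"yes": -1, "no": 1, "unknown": 0},
    "Q7": {"yes": 1, "no": 0, "unknown": 0},
    "Q8": {"yes": 1, "no": 0, "unknown": 0},
    "Q9": {"yes": 1, "no": 0, "unknown": 0},
    "Q10": {"yes": 1, "no": 0, "unknown": 0}
  },
  "boundaries": {
    "comment": "Upper (inclusive) total-score bound of each category except the top one: total <= 0 -> unlikely, 1-4 -> possible, 5-8 -> probable, >= 9 -> definite.",
    "unlikely": 0,
    "possible": 4,
    "probable": 8
  }
}
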