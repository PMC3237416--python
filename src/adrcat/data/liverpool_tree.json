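{
  "metadata": {
    "name": "liverpool-adr-cat",
    "version": "1.0",
    "description": "Default Liverpool ADR causality assessment tool: a flowchart of mostly dichotomous questions routing to one of four causality categories. Re-challenge recurrence (or a previous reaction to the same drug) is required to reach Definite.",
    "transcription_notes": [
      "The published flowchart is available only as a figure; this document reconstructs its logic from the accompanying narrative rather than transcribing the figure verbatim.",
      "The alternative-cause question is ternary: 'unsure' prompts the assessor to seek further evidence and, pending that, routes to Possible.",
      "A failed or absent de-challenge routes to Possible rather than Unlikely, because events with irreversible sequelae need not improve on withdrawal.",
      "Previous reaction on exposure to the same drug is given the same weight as a positive prospective re-challenge and shares the Definite gate node."
    ]
  },
  "root": "temporal",
  "nodes": [
    {
      "id": "temporal",
      "prompt": "Did the adverse event occur after the suspected drug was administered?",
      "routes": {
        "yes": {"node": "alt_cause"},
        "no": {"leaf": "unlikely_no_temporal"}
      }
    },
    {
      "id": "alt_cause",
      "prompt": "Is the adverse event more likely to be due to an alternative cause (underlying illness, another drug or treatment) than the suspected drug?",
      "routes": {
        "yes": {"leaf": "unlikely_alt_cause"},
        "unsure": {"leaf": "possible_unsure"},
        "no": {"node": "dechallenge"}
      }
    },
    {
      "id": "dechallenge",
      "prompt": "Was the suspected drug withdrawn or the dose reduced (de-challenge)?",
      "routes": {
        "yes": {"node": "improvement"},
        "no": {"leaf": "possible_no_dechallenge"}
      }
    },
    {
      "id": "improvement",
      "prompt": "Did the adverse event improve after the drug was withdrawn or the dose reduced (taking account of events with irreversible sequelae)?",
      "routes": {
        "yes": {"node": "rechallenge"},
        "no": {"leaf": "possible_no_improvement"}
      }
    },
    {
      "id": "rechallenge",
      "prompt": "Did the adverse event recur when the drug was re-administered, or has the patient previously had a similar reaction on exposure to the same drug?",
      "tags": {"rechallenge_gate": "yes"},
      "routes": {
        "yes": {"leaf": "definite_rechallenge"},
        "no": {"leaf": "probable_no_rechallenge"}
      }
    }
  ],
  "leaves": [
    {"id": "unlikely_no_temporal", "category": "unlikely"},
    {"id": "unlikely_alt_cause", "category": "unlikely"},
    {"id": "possible_unsure", "category": "possible"},
    {"id": "possible_no_dechallenge", "category": "possible"},
    {"id": "possible_no_improvement", "category": "possible"},
    {"id": "probable_no_rechallenge", "category": "probable"},
    {"id": "definite_rechallenge", "category": "definite"}
  ]
}
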