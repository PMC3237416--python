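{
  "description": "Published per-assessor causality category counts from the development and internal validation of the Liverpool ADR causality assessment tool: a panel of seven assessors (anonymised A1-A7) rating suspected-ADR admissions from a paediatric observational study (an original and a new set of 40 cases, each rated with both the Naranjo and Liverpool instruments) and 37 published pharmacotherapy case reports (Liverpool only; the reports' own authors supplied one Naranjo assessment per case). Development-iteration arms retain only the collated panel counts.",
  "categories": ["unlikely", "possible", "probable", "definite"],
  "arms": {
    "observational_original_naranjo": {
      "instrument": "naranjo",
      "n_cases": 40,
      "per_assessor": {
        "A1": [0, 18, 22, 0],
        "A2": [0, 17, 22, 1],
        "A3": [0, 18, 21, 1],
        "A4": [0, 14, 24, 2],
        "A5": [0, 10, 29, 1],
        "A6": [0, 12, 27, 1],
        "A7": [0, 11, 27, 2]
      }
    },
    "observational_original_liverpool": {
      "instrument": "liverpool",
      "n_cases": 40,
      "per_assessor": {
        "A1": [0, 7, 23, 10],
        "A2": [0, 15, 8, 17],
        "A3": [0, 18, 4, 18],
        "A4": [1, 5, 17, 17],
        "A5": [0, 3, 15, 22],
        "A6": [0, 7, 12, 21],
        "A7": [0, 7, 13, 20]
      }
    },
    "case_reports_liverpool": {
      "instrument": "liverpool",
      "n_cases": 37,
      "per_assessor": {
        "A1": [0, 11, 18, 8],
        "A2": [0, 11, 20, 6],
        "A3": [0, 12, 19, 6],
        "A4": [0, 10, 18, 9],
        "A5": [1, 10, 20, 6],
        "A6": [0, 10, 17, 10],
        "A7": [0, 3, 24, 10]
      }
    },
    "case_reports_authors_naranjo": {
      "instrument": "naranjo",
      "n_cases": 37,
      "per_assessor": {
        "authors": [0, 5, 29, 3]
      }
    },
    "observational_new_naranjo": {
      "instrument": "naranjo",
      "n_cases": 40,
      "per_assessor": {
        "A1": [0, 18, 21, 1],
        "A2": [0, 19, 21, 0],
        "A3": [0, 15, 25, 0],
        "A4": [1, 9, 27, 3],
        "A5": [0, 13, 27, 0],
        "A6": [0, 12, 28, 0],
        "A7": [0, 4, 36, 0]
      }
    },
    "observational_new_liverpool": {
      "instrument": "liverpool",
      "n_cases": 40,
      "per_assessor": {
        "A1": [0, 11, 12, 17],
        "A2": [0, 14, 8, 18],
        "A3": [0, 13, 10, 17],
        "A4": [0, 8, 9, 23],
        "A5": [0, 8, 12, 20],
        "A6": [0, 9, 13, 18],
        "A7": [0, 3, 17, 20]
      }
    },
    "iteration1_prototype_liverpool": {
      "instrument": "liverpool-prototype-1",
      "n_cases": 20,
      "per_assessor": {
        "panel": [1, 18, 2, 119]
      }
    },
    "iteration2_prototype_observational": {
      "instrument": "liverpool-prototype-2",
      "n_cases": 10,
      "per_assessor": {
        "panel": [0, 24, 39, 7]
      }
    },
    "iteration2_prototype_adult": {
      "instrument": "liverpool-prototype-2",
      "n_cases": 10,
      "per_assessor": {
        "panel": [0, 13, 48, 9]
      }
    }
  }
}
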