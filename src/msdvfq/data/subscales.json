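{
  "_comment": "Default item -> subscale assignment and 0-100 recode values for the legacy composite score, shipped as configuration data (standard scoring-manual content, replaceable by the user). The composite averages the 11 subscale scores other than general health; subscales with no rated item drop out of the average.",
  "subscales": {
    "general_health": {
      "in_composite": false,
      "items": {"q1": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0}}
    },
    "general_vision": {
      "in_composite": true,
      "items": {"q2": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0}}
    },
    "ocular_pain": {
      "in_composite": true,
      "items": {
        "q4": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
        "q19": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100}
      }
    },
    "near_activities": {
      "in_composite": true,
      "items": {
        "q5": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q6": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q7": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}
      }
    },
    "distance_activities": {
      "in_composite": true,
      "items": {
        "q8": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q9": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q14": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}
      }
    },
    "social_functioning": {
      "in_composite": true,
      "items": {
        "q11": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q13": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}
      }
    },
    "mental_health": {
      "in_composite": true,
      "items": {
        "q3": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
        "q21": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
        "q22": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
        "q25": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100}
      }
    },
    "role_difficulties": {
      "in_composite": true,
      "items": {
        "q17": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
        "q18": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100}
      }
    },
    "dependency": {
      "in_composite": true,
      "items": {
        "q20": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
        "q23": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
        "q24": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100}
      }
    },
    "driving": {
      "in_composite": true,
      "items": {
        "q15c": {"1": 100, "2": 75, "3": 50, "4": 25},
        "q16": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null},
        "q16a": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}
      }
    },
    "color_vision": {
      "in_composite": true,
      "items": {"q12": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}}
    },
    "peripheral_vision": {
      "in_composite": true,
      "items": {"q10": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0, "6": null}}
    }
  }
}
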