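{
  "_comment": "Raw-option -> category recode tables for the native NEI VFQ-25 (+appendix) option numbering. Categories are oriented so that a higher category means greater function; null maps an opt-out option to missing. The per-type option lists are standard questionnaire content reproduced here as reviewable configuration data.",
  "tables": {
    "difficulty6": {
      "_options": "1 no difficulty, 2 a little, 3 moderate, 4 extreme, 5 stopped because of eyesight, 6 stopped for other reasons / not interested",
      "1": 4, "2": 3, "3": 2, "4": 1, "5": 0, "6": null
    },
    "frequency5_reverse": {
      "_options": "1 none of the time ... 5 all of the time (item asks how often a problem occurs, so more frequent = less function)",
      "1": 4, "2": 3, "3": 2, "4": 1, "5": 0
    },
    "severity5_reverse": {
      "_options": "1 none, 2 mild, 3 moderate, 4 severe, 5 very severe",
      "1": 4, "2": 3, "3": 2, "4": 1, "5": 0
    },
    "agreement5": {
      "_options": "1 definitely true ... 5 definitely false (statements describe a problem, so definitely false = greatest function)",
      "1": 0, "2": 1, "3": 2, "4": 3, "5": 4
    },
    "driving4": {
      "_options": "q15c: 1 no difficulty ... 4 extreme difficulty (asked of current drivers only; category 0 is supplied by respondents who stopped driving because of eyesight)",
      "1": 4, "2": 3, "3": 2, "4": 1
    }
  },
  "driving": {
    "_comment": "Gating items for the collapsed driving item (converted item 30) and the other driving items (16, 16A). q15: currently driving (1 yes / 2 no); q15a: 1 never drove / 2 gave up; q15b reason for giving up: 1 mainly eyesight, 2 mainly other reasons, 3 both.",
    "current_driver": 1,
    "not_driving": 2,
    "never_drove": 1,
    "gave_up": 2,
    "stopped_eyesight": 1,
    "stopped_other_codes": [2, 3]
  }
}
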