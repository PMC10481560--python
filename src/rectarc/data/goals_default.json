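[
 {"roi": "PTV", "metric": "Dx", "parameter": 93, "comparator": ">", "threshold": 98, "unit": "pct_rx", "scope": "per_plan"},
 {"roi": "PTV", "metric": "Dx", "parameter": 2, "comparator": "<", "threshold": 110, "unit": "pct_rx", "scope": "per_plan"},
 {"roi": "SmallBowel", "metric": "Vx", "parameter": 35, "comparator": "<", "threshold": 230, "unit": "cc", "scope": "plan_sum"},
 {"roi": "SmallBowel", "metric": "Vx", "parameter": 40, "comparator": "<", "threshold": 130, "unit": "cc", "scope": "plan_sum"},
 {"roi": "SmallBowel", "metric": "Vx", "parameter": 45, "comparator": "<", "threshold": 90, "unit": "cc", "scope": "plan_sum"},
 {"roi": "Bladder", "metric": "Vx", "parameter": 40, "comparator": "<", "threshold": 55, "unit": "pct_volume", "scope": "plan_sum"},
 {"roi": "Bladder", "metric": "Vx", "parameter": 45, "comparator": "<", "threshold": 30, "unit": "pct_volume", "scope": "plan_sum"},
 {"roi": "Bladder", "metric": "Vx", "parameter": 50, "comparator": "<=", "threshold": 0, "unit": "pct_volume", "scope": "plan_sum"},
 {"roi": "FemoralHeads", "metric": "Vx", "parameter": 40, "comparator": "<", "threshold": 65, "unit": "pct_volume", "scope": "plan_sum"},
 {"roi": "FemoralHeads", "metric": "Vx", "parameter": 45, "comparator": "<", "threshold": 45, "unit": "pct_volume", "scope": "plan_sum"},
 {"roi": "FemoralHeads", "metric": "Vx", "parameter": 50, "comparator": "<=", "threshold": 0, "unit": "pct_volume", "scope": "plan_sum"}
]
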