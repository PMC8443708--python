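{
  "basis": "UK NHS + PSS perspective, 2018/19 GBP, costs and QALYs discounted at 3.5%/yr (payoffs pre-discounted, not recomputed here)",
  "prevalence": {
    "family": "beta", "params": {"a": 41, "b": 238}, "printed_mean": 0.15,
    "note": "proximal DVT prevalence in suspected-DVT referrals"
  },
  "wells": {
    "cost": {
      "family": "gamma", "params": {"shape": 25, "scale": 0.34}, "printed_mean": 9.66,
      "note": "printed mean inconsistent with gamma parameters (25*0.34 = 8.50); deterministic runs use the printed mean"
    },
    "dvt_split": {
      "family": "dirichlet",
      "params": {"counts": [105.61, 38.83, 10.87]},
      "categories": ["high", "moderate", "low"],
      "printed_means": [0.68, 0.25, 0.07]
    },
    "no_dvt_split": {
      "family": "dirichlet",
      "params": {"counts": [40.78, 151.99, 177.94]},
      "categories": ["high", "moderate", "low"],
      "printed_means": [0.11, 0.41, 0.48]
    }
  },
  "d_dimer": {
    "cost": {"family": "gamma", "params": {"shape": 25, "scale": 0.78}, "printed_mean": 19.5},
    "sensitivity": {"family": "beta", "params": {"a": 736.91, "b": 15.04}, "printed_mean": 0.98},
    "specificity_by_wells": {
      "high": {"family": "fixed", "params": {"value": 0.34}, "printed_mean": 0.34},
      "moderate": {"family": "beta", "params": {"a": 4278.13, "b": 5228.83}, "printed_mean": 0.45},
      "low": {"family": "fixed", "params": {"value": 0.52}, "printed_mean": 0.52}
    }
  },
  "ultrasound": {
    "cost": {
      "family": "gamma", "params": {"shape": 319.23, "scale": 0.25}, "printed_mean": 77.19,
      "note": "printed mean inconsistent with gamma parameters (319.23*0.25 = 79.81); deterministic runs use the printed mean"
    },
    "sensitivity": {"family": "fixed", "params": {"value": 0.95}, "printed_mean": 0.95},
    "specificity": {"family": "fixed", "params": {"value": 0.94}, "printed_mean": 0.94}
  },
  "treated_dvt": {
    "fatal_pe": {
      "family": "beta", "params": {"a": 174, "b": 204}, "printed_mean": 0.0,
      "note": "printed mean 0 is inconsistent with Beta(174, 204); both preserved, deterministic runs use the printed mean"
    },
    "nonfatal_pe": {"family": "beta", "params": {"a": 33.4, "b": 4070.6}, "printed_mean": 0.01},
    "pts": {"family": "beta", "params": {"a": 28, "b": 500}, "printed_mean": 0.05},
    "warfarin_split": {
      "family": "dirichlet",
      "params": {"counts": [37, 13, 226, 10481]},
      "categories": ["fatal_haemorrhage", "nonfatal_intracranial_haemorrhage", "nonfatal_nonintracranial_haemorrhage", "no_haemorrhage"],
      "printed_means": [0.0, 0.0, 0.02, 0.98],
      "note": "no-haemorrhage printed mean 0.98 differs from the count-implied 0.974; counts are used in analysis"
    }
  },
  "untreated_dvt": {
    "fatal_pe": {"family": "beta", "params": {"a": 5, "b": 263}, "printed_mean": 0.02},
    "nonfatal_pe": {"family": "beta", "params": {"a": 25, "b": 243}, "printed_mean": 0.09},
    "pts": {"family": "beta", "params": {"a": 5.21, "b": 10.57}, "printed_mean": 0.33}
  },
  "utilities": {
    "base_qale": {"family": "fixed", "params": {"value": 11.6}, "printed_mean": 11.6},
    "nonfatal_pe": {"family": "beta", "params": {"a": 19.43, "b": 1.24}, "printed_mean": 0.94},
    "nonfatal_intracranial_haemorrhage": {"family": "beta", "params": {"a": 8.34, "b": 20.41}, "printed_mean": 0.29},
    "pts": {"family": "beta", "params": {"a": 232.64, "b": 5.48}, "printed_mean": 0.98}
  },
  "event_costs": {
    "fatal_pe": 1650,
    "nonfatal_pe": 1601,
    "pts": 4663,
    "fatal_haemorrhage": 9334,
    "nonfatal_intracranial_haemorrhage": 64147,
    "nonfatal_nonintracranial_haemorrhage": 805
  },
  "treatment_cost": 845,
  "payoffs": {
    "tp": {"qalys": 11.464, "cost": 1321},
    "fn": {"qalys": 11.207, "cost": 2214},
    "fp": {"qalys": 11.530, "cost": 975},
    "tn": {"qalys": 11.580, "cost": 0}
  },
  "table6_rows": {
    "no_software_support": {"tp": 0.10, "fp": 0.06, "tn": 0.84, "fn": 0.00},
    "algorithm_1": {"tp": 0.09, "fp": 0.015, "tn": 0.885, "fn": 0.01},
    "algorithm_2": {"tp": 0.09, "fp": 0.015, "tn": 0.885, "fn": 0.01},
    "algorithm_3": {"tp": 0.09, "fp": 0.015, "tn": 0.885, "fn": 0.01}
  }
}
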