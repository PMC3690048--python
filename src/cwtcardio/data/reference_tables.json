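{
  "description": "Published per-user evaluation tables for the wearable-ECG / SCR stress study this package reimplements. Confusion-matrix convention: tp = row T col P, fn = row T col N, fp = row F col P, tn = row F col N. 'precision' in the printed statistics is overall accuracy (TP+TN)/total. The user-2 R-wave FN cell is blank in print; the printed sensitivity of 1 implies fn = 0.",
  "r_wave": {
    "user1": {"tp": 117, "fn": 6, "fp": 0, "tn": 32901},
    "user2": {"tp": 538, "fn": 0, "fp": 0, "tn": 101606},
    "user3": {"tp": 519, "fn": 0, "fp": 0, "tn": 101625},
    "user4": {"tp": 217, "fn": 1, "fp": 0, "tn": 53458},
    "user5": {"tp": 229, "fn": 2, "fp": 10, "tn": 101903},
    "user6": {"tp": 444, "fn": 0, "fp": 3, "tn": 101697},
    "user7": {"tp": 523, "fn": 0, "fp": 0, "tn": 101621},
    "user8": {"tp": 292, "fn": 0, "fp": 0, "tn": 78710},
    "user9": {"tp": 245, "fn": 0, "fp": 0, "tn": 44800},
    "user10": {"tp": 306, "fn": 0, "fp": 0, "tn": 90162},
    "user11": {"tp": 551, "fn": 1, "fp": 0, "tn": 95460},
    "user12": {"tp": 327, "fn": 2, "fp": 0, "tn": 78610}
  },
  "r_wave_stats": {
    "user1": {"sensitivity": 0.9512, "specificity": 1.0, "precision": 0.9998},
    "user2": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user3": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user4": {"sensitivity": 0.9954, "specificity": 1.0, "precision": 0.99998},
    "user5": {"sensitivity": 0.9913, "specificity": 0.9999, "precision": 0.9999},
    "user6": {"sensitivity": 1.0, "specificity": 0.99997, "precision": 0.99997},
    "user7": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user8": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user9": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user10": {"sensitivity": 1.0, "specificity": 1.0, "precision": 1.0},
    "user11": {"sensitivity": 0.9982, "specificity": 1.0, "precision": 0.99999},
    "user12": {"sensitivity": 0.9939, "specificity": 1.0, "precision": 0.99997}
  },
  "headline_mean_r_sensitivity_pct": 99.42,
  "extrasystole": {
    "test1": {"tp": 189, "fn": 0, "fp": 0, "tn": 210},
    "test2": {"tp": 348, "fn": 0, "fp": 0, "tn": 702},
    "test3": {"tp": 225, "fn": 8, "fp": 0, "tn": 236},
    "test4": {"tp": 362, "fn": 0, "fp": 0, "tn": 722}
  },
  "extrasystole_stats_pct": {
    "test1": {"sensitivity": 100.0, "specificity": 100.0},
    "test2": {"sensitivity": 100.0, "specificity": 100.0},
    "test3": {"sensitivity": 96.57, "specificity": 100.0},
    "test4": {"sensitivity": 100.0, "specificity": 100.0},
    "total": {"sensitivity": 99.29, "specificity": 100.0}
  },
  "arrhythmia": {
    "test1": {"tp": 16, "fn": 1, "fp": 0, "tn": 517},
    "test2": {"tp": 7, "fn": 0, "fp": 0, "tn": 401},
    "test3": {"tp": 20, "fn": 2, "fp": 0, "tn": 318}
  },
  "arrhythmia_stats_pct": {
    "test1": {"sensitivity": 94.12, "specificity": 100.0},
    "test2": {"sensitivity": 100.0, "specificity": 100.0},
    "test3": {"sensitivity": 90.91, "specificity": 100.0},
    "total": {"sensitivity": 93.48, "specificity": 100.0}
  },
  "scr_stroop": {
    "user4": {"tp": 221, "fn": 15, "fp": 1, "tn": 212},
    "user7": {"tp": 234, "fn": 2, "fp": 1, "tn": 231},
    "user8": {"tp": 134, "fn": 4, "fp": 18, "tn": 215},
    "user9": {"tp": 165, "fn": 1, "fp": 16, "tn": 216},
    "user12": {"tp": 235, "fn": 1, "fp": 3, "tn": 155}
  },
  "scr_stroop_stats_pct": {
    "user4": {"correct": 96.44, "incorrect": 3.56, "error": 12.91, "success": 87.09},
    "user7": {"correct": 99.34, "incorrect": 0.641, "error": 2.08, "success": 97.92},
    "user8": {"correct": 94.07, "incorrect": 5.93, "error": 18.54, "success": 81.46},
    "user9": {"correct": 95.72, "incorrect": 4.27, "error": 15.61, "success": 84.39},
    "user12": {"correct": 98.98, "incorrect": 1.02, "error": 3.14, "success": 96.86}
  },
  "scr_stroop_means_V": {
    "user4": {"stress": 0.7026, "relax": 0.6775},
    "user7": {"stress": 1.3011, "relax": 1.2647},
    "user8": {"stress": 0.8597, "relax": 0.8093},
    "user9": {"stress": 1.2106, "relax": 1.1834},
    "user12": {"stress": 1.0849, "relax": 1.055}
  },
  "scr_sounds": {
    "user2": {"tp": 33, "fn": 0, "fp": 1, "tn": 683},
    "user3": {"tp": 425, "fn": 7, "fp": 4, "tn": 294},
    "user5": {"tp": 707, "fn": 0, "fp": 1, "tn": 319},
    "user6": {"tp": 228, "fn": 3, "fp": 6, "tn": 391},
    "user10": {"tp": 437, "fn": 0, "fp": 1, "tn": 507},
    "user11": {"tp": 715, "fn": 0, "fp": 3, "tn": 353},
    "user12": {"tp": 511, "fn": 0, "fp": 1, "tn": 450}
  },
  "scr_sounds_stats_pct": {
    "user2": {"correct": 99.86, "incorrect": 0.14, "error": 1.57, "success": 98.43},
    "user3": {"correct": 98.49, "incorrect": 1.51, "error": 4.31, "success": 95.69},
    "user5": {"correct": 99.90, "incorrect": 0.10, "error": 0.23, "success": 99.77},
    "user6": {"correct": 98.57, "incorrect": 1.43, "error": 4.60, "success": 95.40},
    "user10": {"correct": 99.89, "incorrect": 0.11, "error": 0.21, "success": 99.79},
    "user11": {"correct": 99.72, "incorrect": 0.28, "error": 0.63, "success": 99.37},
    "user12": {"correct": 99.90, "incorrect": 0.10, "error": 0.21, "success": 99.79}
  },
  "scr_sounds_means_V": {
    "user2": {"stress": 1.1370, "relax": 0.6312},
    "user3": {"stress": 0.794, "relax": 0.6549},
    "user5": {"stress": 1.2971, "relax": 1.232},
    "user6": {"stress": 1.137, "relax": 0.9741},
    "user10": {"stress": 1.3824, "relax": 1.3482},
    "user11": {"stress": 1.2483, "relax": 1.1457},
    "user12": {"stress": 1.1113, "relax": 1.0158}
  },
  "stress_test_averages_pct": {"stroop": 89.74, "sounds": 98.32, "total": 94.02},
  "hr_sd_stroop": {
    "user4": {"before": 0.0697, "during": 0.0527, "after": 0.0502},
    "user7": {"before": 0.0831, "during": 0.0268, "after": 0.0308},
    "user8": {"before": 0.1473, "during": 0.0413, "after": 0.0585},
    "user9": {"before": 0.0429, "during": 0.0310, "after": 0.0551},
    "user12": {"before": 0.1015, "during": 0.0789, "after": 0.0720}
  }
}
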