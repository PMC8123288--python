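{
 "cases": {
  "1": {
   "baseline": {
    "afp_ng_ml": 21531,
    "pivka_mau_ml": 30362,
    "ttv_cm3": 139
   },
   "c0": 1780000.0,
   "duration_months": 60,
   "overall_response": "CR",
   "params": {
    "alpha2": 0.0042,
    "alpha3": 0.35,
    "kappa": 25611.5,
    "mu1": 1.3e-05,
    "mu2": 0.5,
    "omega1": 0.0022,
    "omega2": 0.1,
    "pi1": 0.00025,
    "pi2": 1.22,
    "pi3": 0.2,
    "psi1": 10,
    "theta1": 220,
    "xi1": 0.36,
    "xi2": 0.931,
    "xi4": 0.11
   },
   "response": "CR",
   "treatment": "sorafenib"
  },
  "10": {
   "baseline": {
    "afp_ng_ml": 1167,
    "pivka_mau_ml": 4712,
    "ttv_cm3": 116
   },
   "c0": null,
   "duration_months": 5.7,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0,
    "mu1": 7e-06,
    "mu2": 0.4,
    "omega1": 0.0001,
    "omega2": 0.1,
    "pi1": 0.0002,
    "pi2": 1.14,
    "pi3": 0.4,
    "psi1": 0,
    "theta1": 1,
    "xi1": 0.355,
    "xi2": 0.923,
    "xi4": 0.11
   },
   "response": "PD",
   "treatment": "sorafenib"
  },
  "2": {
   "baseline": {
    "afp_ng_ml": 5905,
    "pivka_mau_ml": 108460,
    "ttv_cm3": 32
   },
   "c0": 3170000.0,
   "duration_months": 27,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.0042,
    "alpha3": 0.27,
    "kappa": 198125.0,
    "mu1": 1.3e-05,
    "mu2": 0.5,
    "omega1": 0.0015,
    "omega2": 0.1,
    "pi1": 0.01,
    "pi2": 1.15,
    "pi3": 0.3,
    "psi1": 5,
    "theta1": 50,
    "xi1": 0.25,
    "xi2": 0.959,
    "xi4": 0.11
   },
   "response": "PR",
   "treatment": "sorafenib"
  },
  "3": {
   "baseline": {
    "afp_ng_ml": 29953,
    "pivka_mau_ml": 592,
    "ttv_cm3": 52.2
   },
   "c0": 579000.0,
   "duration_months": 12,
   "overall_response": "PR",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0.002,
    "kappa": 22183.9,
    "mu1": 7e-06,
    "mu2": 0.4,
    "omega1": 0.0065,
    "omega2": 0.1,
    "pi1": 7e-05,
    "pi2": 1.14,
    "pi3": 0.4,
    "pi4": 15,
    "pi5": 1.52,
    "psi1": 5,
    "theta1": 30,
    "xi1": 0.32,
    "xi2": 0.932,
    "xi4": 0.11
   },
   "response": "PR",
   "treatment": "regorafenib"
  },
  "4": {
   "baseline": {
    "afp_ng_ml": 635,
    "pivka_mau_ml": 151,
    "ttv_cm3": 6.4
   },
   "c0": null,
   "duration_months": 11.5,
   "overall_response": "CR",
   "params": {
    "alpha2": 0.004,
    "alpha3": 0.2,
    "mu1": 3e-05,
    "mu2": 0.4,
    "omega1": 0.001,
    "omega2": 0.1,
    "pi1": 0.0002,
    "pi2": 1.14,
    "pi3": 0.4,
    "psi1": 10,
    "theta1": 500,
    "xi1": 0.317,
    "xi2": 0.917,
    "xi4": 0.12
   },
   "response": "CR",
   "treatment": "sorafenib"
  },
  "5": {
   "baseline": {
    "afp_ng_ml": 513,
    "pivka_mau_ml": 388,
    "ttv_cm3": 24.5
   },
   "c0": null,
   "duration_months": 25.7,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0.4,
    "mu1": 5e-06,
    "mu2": 0.4,
    "omega1": 0.0002,
    "omega2": 0.1,
    "pi1": 0.0002,
    "pi2": 1.2,
    "pi3": 0.4,
    "psi1": 70,
    "theta1": 150,
    "xi1": 0.315,
    "xi2": 0.91,
    "xi4": 0.11
   },
   "response": "CR",
   "treatment": "sorafenib"
  },
  "6": {
   "baseline": {
    "afp_ng_ml": 1741,
    "pivka_mau_ml": 147,
    "ttv_cm3": 6.1
   },
   "c0": null,
   "duration_months": 18.4,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0.2,
    "mu1": 9e-05,
    "mu2": 0.4,
    "omega1": 0.003,
    "omega2": 0.12,
    "pi1": 0.098,
    "pi2": 0.62,
    "pi3": 0.5,
    "psi1": 50,
    "theta1": 100,
    "xi1": 0.315,
    "xi2": 0.911,
    "xi4": 0.11
   },
   "response": "CR",
   "treatment": "sorafenib"
  },
  "7": {
   "baseline": {
    "afp_ng_ml": 55,
    "pivka_mau_ml": 6000,
    "ttv_cm3": 200
   },
   "c0": null,
   "duration_months": 9.3,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0,
    "mu1": 8e-06,
    "mu2": 0.4,
    "omega1": 7e-06,
    "omega2": 0.3,
    "pi1": 0.003,
    "pi2": 0.88,
    "pi3": 0.2,
    "psi1": 10,
    "theta1": 30,
    "xi1": 0.36,
    "xi2": 0.924,
    "xi4": 0.11
   },
   "response": "SD",
   "treatment": "sorafenib"
  },
  "8": {
   "baseline": {
    "afp_ng_ml": 71,
    "pivka_mau_ml": 589,
    "ttv_cm3": 89
   },
   "c0": null,
   "duration_months": 18.9,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0,
    "mu1": 7e-06,
    "mu2": 0.4,
    "omega1": 6e-06,
    "omega2": 0.1,
    "pi1": 5e-05,
    "pi2": 1.13,
    "pi3": 0.4,
    "psi1": 3,
    "theta1": 13,
    "xi1": 0.33,
    "xi2": 0.926,
    "xi4": 0.11
   },
   "response": "SD",
   "treatment": "sorafenib"
  },
  "9": {
   "baseline": {
    "afp_ng_ml": 417,
    "pivka_mau_ml": 9799,
    "ttv_cm3": 29.1
   },
   "c0": null,
   "duration_months": 5.1,
   "overall_response": "PD",
   "params": {
    "alpha2": 0.002,
    "alpha3": 0,
    "mu1": 7e-06,
    "mu2": 0.4,
    "omega1": 0.0003,
    "omega2": 0.1,
    "pi1": 0.008,
    "pi2": 1.0,
    "pi3": 0.4,
    "psi1": 1,
    "theta1": 3,
    "xi1": 0.44,
    "xi2": 0.9,
    "xi4": 0.11
   },
   "response": "PD",
   "treatment": "sorafenib"
  }
 },
 "format": "hccdyn-case-fixtures",
 "version": 1
}
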