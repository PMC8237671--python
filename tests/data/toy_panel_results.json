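{
  "gap": {
    "gap_pp": 42.0,
    "wave2_support_enforced": 0.4,
    "wave2_support_voluntary": 0.82
  },
  "likert": {
    "enforced": {
      "item": "enforced",
      "waves": {
        "1": {
          "ci": [
            2.0112738475,
            2.9087261525
          ],
          "cumulative": {
            "1": 0.78,
            "2": 0.7,
            "3": 0.56,
            "4": 0.42
          },
          "mean": 2.46,
          "n": 50,
          "opposition_share": 0.3
        },
        "2": {
          "ci": [
            1.3914455299,
            2.3285544701
          ],
          "cumulative": {
            "1": 0.66,
            "2": 0.5,
            "3": 0.4,
            "4": 0.3
          },
          "mean": 1.86,
          "n": 50,
          "opposition_share": 0.5
        }
      }
    },
    "voluntary": {
      "item": "voluntary",
      "waves": {
        "1": {
          "ci": [
            2.3160303941,
            3.1239696059
          ],
          "cumulative": {
            "1": 0.86,
            "2": 0.8,
            "3": 0.6,
            "4": 0.46
          },
          "mean": 2.72,
          "n": 50,
          "opposition_share": 0.2
        },
        "2": {
          "ci": [
            3.0236737268,
            3.4963262732
          ],
          "cumulative": {
            "1": 1.0,
            "2": 0.96,
            "3": 0.82,
            "4": 0.48
          },
          "mean": 3.26,
          "n": 50,
          "opposition_share": 0.04
        }
      }
    }
  },
  "regressions": {
    "A_enforced": {
      "coefficients": {
        "altruism": 0.1198909804,
        "east": 0.075207401,
        "female": -0.1933687411,
        "pandemic_critical": 0.2351663566,
        "trust": 0.4673944017
      },
      "conf_int": {
        "altruism": [
          -0.1486198961,
          0.388401857
        ],
        "east": [
          -0.1925498454,
          0.3429646474
        ],
        "female": [
          -0.4589351533,
          0.0721976711
        ],
        "pandemic_critical": [
          -0.0342975675,
          0.5046302806
        ],
        "trust": [
          0.1957268479,
          0.7390619555
        ]
      },
      "model_id": "A",
      "n": 50,
      "outcome": "enforced_wave2",
      "raw_coefficients": {
        "altruism": 0.1943588656,
        "east": 0.3038169317,
        "female": -0.6605271654,
        "pandemic_critical": 0.3550162,
        "trust": 0.771945299
      }
    },
    "A_voluntary": {
      "coefficients": {
        "altruism": 0.2044480919,
        "east": -0.2078939939,
        "female": 0.3553702467,
        "pandemic_critical": 0.2407451494,
        "trust": 0.3021973637
      },
      "conf_int": {
        "altruism": [
          -0.0549873382,
          0.463883522
        ],
        "east": [
          -0.466601266,
          0.0508132781
        ],
        "female": [
          0.0987797605,
          0.6119607329
        ],
        "pandemic_critical": [
          -0.019611116,
          0.5011014147
        ],
        "trust": [
          0.0397119494,
          0.5646827779
        ]
      },
      "model_id": "A",
      "n": 50,
      "outcome": "voluntary_wave2",
      "raw_coefficients": {
        "altruism": 0.1671678767,
        "east": -0.4235895684,
        "female": 0.6122621304,
        "pandemic_critical": 0.1833084338,
        "trust": 0.2517361655
      }
    },
    "B_enforced": {
      "coefficients": {
        "altruism": 0.1755423106,
        "east": 0.0406917537,
        "effectiveness": 0.2631480416,
        "female": -0.2718574254,
        "freedom": -0.1303451647,
        "pandemic_critical": 0.2669200937,
        "trust": 0.5078697623
      },
      "conf_int": {
        "altruism": [
          -0.0924295747,
          0.4435141959
        ],
        "east": [
          -0.2243196711,
          0.3057031784
        ],
        "effectiveness": [
          -0.0150028065,
          0.5412988898
        ],
        "female": [
          -0.5458139143,
          0.0020990634
        ],
        "freedom": [
          -0.3925773405,
          0.131887011
        ],
        "pandemic_critical": [
          0.0019085069,
          0.5319316805
        ],
        "trust": [
          0.2395895419,
          0.7761499826
        ]
      },
      "model_id": "B",
      "n": 50,
      "outcome": "enforced_wave2",
      "raw_coefficients": {
        "altruism": 0.2845769067,
        "east": 0.1643833396,
        "effectiveness": 0.4773951119,
        "female": -0.9286362087,
        "freedom": -0.2279008133,
        "pandemic_critical": 0.4029528661,
        "trust": 0.8387941192
      }
    },
    "B_voluntary": {
      "coefficients": {
        "altruism": 0.233463732,
        "east": -0.241734687,
        "effectiveness": 0.017795117,
        "female": 0.3594231087,
        "freedom": -0.2253024881,
        "pandemic_critical": 0.2482801811,
        "trust": 0.3126984184
      },
      "conf_int": {
        "altruism": [
          -0.0286488773,
          0.4955763412
        ],
        "east": [
          -0.500951567,
          0.017482193
        ],
        "effectiveness": [
          -0.2542738894,
          0.2898641235
        ],
        "female": [
          0.0914567508,
          0.6273894665
        ],
        "freedom": [
          -0.4818008881,
          0.0311959119
        ],
        "pandemic_critical": [
          -0.0109368573,
          0.5074972196
        ],
        "trust": [
          0.0502842159,
          0.5751126209
        ]
      },
      "model_id": "B",
      "n": 50,
      "outcome": "voluntary_wave2",
      "raw_coefficients": {
        "altruism": 0.1908926418,
        "east": -0.4925408849,
        "effectiveness": 0.0162828565,
        "female": 0.6192447462,
        "freedom": -0.1986867282,
        "pandemic_critical": 0.1890457659,
        "trust": 0.2604837444
      }
    },
    "C_enforced": {
      "coefficients": {
        "d_trust": 0.024884006
      },
      "conf_int": {
        "d_trust": [
          -0.2652362587,
          0.3150042707
        ]
      },
      "model_id": "C",
      "n": 50,
      "outcome": "d_enforced",
      "raw_coefficients": {
        "d_trust": 0.0742782963
      }
    },
    "C_voluntary": {
      "coefficients": {
        "d_trust": 0.0240996401
      },
      "conf_int": {
        "d_trust": [
          -0.2660262014,
          0.3142254815
        ]
      },
      "model_id": "C",
      "n": 50,
      "outcome": "d_voluntary",
      "raw_coefficients": {
        "d_trust": 0.0589903756
      }
    }
  },
  "transitions": {
    "enforced": {
      "n": 50,
      "share_became_supporters_among_prior_nonsupporters": 0.2272727273,
      "share_increased_any": 0.16,
      "share_level0": {
        "1": 0.22,
        "2": 0.34
      },
      "share_reduced_any": 0.4,
      "share_withdrew_among_prior_supporters": 0.4642857143
    },
    "voluntary": {
      "n": 50,
      "share_became_supporters_among_prior_nonsupporters": 0.95,
      "share_increased_any": 0.46,
      "share_level0": {
        "1": 0.14,
        "2": 0.0
      },
      "share_reduced_any": 0.24,
      "share_withdrew_among_prior_supporters": 0.2666666667
    }
  }
}
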