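{
  "scenario": {
    "n_sites": 5,
    "years": [
      2013,
      2014,
      2015,
      2016,
      2017,
      2018,
      2019,
      2020,
      2021
    ],
    "taxa": {
      "porites_massive": 9.0,
      "pocillopora_spp": 5.0,
      "montipora_encrusting": 3.5,
      "pavona_submassive": 2.5,
      "fungia_spp": 2.0,
      "acropora_branching": 1.5,
      "hydnophora": 1.2,
      "other_corals": 4.0
    },
    "dynamics_mode": "independent",
    "sigma_log": 0.25,
    "rho_shared": 0.0,
    "sigma_shared": null,
    "n_points": 2500,
    "seed": 20260921,
    "decline": {
      "start_year": 2018,
      "survival": 0.72
    }
  },
  "note": "synthetic fixture generated by reefsync.simulate.make_fixture"
}
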