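{
  "cell_type": "rat_neostriatal",
  "geometry": {
    "R_cell": 3.3e-06,
    "R_domain": 9.9e-06,
    "d_mem": 5e-09,
    "N_theta": 13,
    "N_r_in": 33,
    "N_r_out": 33
  },
  "electrical": {
    "C_m": 0.01,
    "g1": 2.0,
    "V_rest": -0.07,
    "sigma_i": 0.455,
    "sigma_o": 1.2,
    "T": 310.0
  },
  "pore": {
    "alpha": 1000000000.0,
    "V_ep": 0.258,
    "N0": 1500000000.0,
    "r_star": 5.1e-10,
    "r_m": 8e-10,
    "q_exp": 2.0,
    "D_p": 5e-14,
    "F_max": 7e-10,
    "r_h": 9.7e-10,
    "r_t": 3.1e-10,
    "beta": 1.4e-19,
    "gamma": 1.8e-11,
    "sigma_prime": 0.02,
    "sigma_0": 1e-06
  },
  "atpase": {
    "k1p": 1050.0,
    "k2p": 481.0,
    "k3p": 2000.0,
    "k4p": 320.0,
    "k1m": 172.1,
    "k2m": 20.0,
    "k3m": 2000.0,
    "k4m": 10.0,
    "kd_Nai0": 5.0,
    "kd_Nao0": 0.18,
    "kd_Ki0": 18.8,
    "kd_Ko0": 0.8,
    "kd_MgATP": 0.6,
    "d_Nai": -0.14,
    "d_Nao": 0.44,
    "d_Ki": -0.14,
    "d_Ko": 0.23,
    "c_MgATP": 6.8,
    "c_MgADP": 0.02,
    "c_P": 4.2,
    "pH": 7.09,
    "F_c": 6e-12
  },
  "species": [
    {
      "name": "Na",
      "z": 1,
      "D": 1.33e-09,
      "a": 3.58e-10,
      "c_i0": 12.0,
      "c_o0": 145.0
    },
    {
      "name": "K",
      "z": 1,
      "D": 1.96e-09,
      "a": 3.31e-10,
      "c_i0": 139.0,
      "c_o0": 4.0
    },
    {
      "name": "Ca",
      "z": 2,
      "D": 7.9e-10,
      "a": 4.12e-10,
      "c_i0": 0.0001,
      "c_o0": 2.0
    },
    {
      "name": "Cl",
      "z": -1,
      "D": 2.03e-09,
      "a": 3.32e-10,
      "c_i0": 10.0,
      "c_o0": 110.0
    }
  ],
  "flags": {
    "include_pump_current_in_vm": false,
    "clamp_extracellular": false,
    "lateral_diffusion": false,
    "power_mode": "per_molecule",
    "negative_concentration": "substep"
  }
}
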