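{
  "schema_version": 1,
  "variant": "sequence_dependent",
  "units": {
    "length_nm": 0.8518,
    "energy_kcal_mol": 5.9616,
    "kT_per_kelvin": 0.0003333333333333333
  },
  "geometry": {
    "helix_radius": 0.6,
    "rise": 0.39,
    "twist": 0.62,
    "backbone_offset": -0.4,
    "stack_offset": 0.34,
    "base_offset": 0.4
  },
  "backbone": {
    "eps": 2.0,
    "r0": 0.7241153821560016,
    "delta": 0.25
  },
  "hydrogen_bonding": {
    "eps_AT": 0.88537,
    "eps_GC": 1.23238,
    "a": 8.0,
    "r0": 0.4,
    "r_switch": 0.6,
    "r_cut": 0.85,
    "angle_c0": 0.0
  },
  "stacking": {
    "eps0": 1.3448,
    "eps_kT": 2.6568,
    "a": 6.0,
    "r0": 0.42102687878474626,
    "r_switch": 0.55,
    "r_cut": 0.8,
    "angle_c0": -0.5,
    "factors": {
      "AA": 0.711427,
      "AC": 1.024455,
      "AG": 0.910627,
      "AT": 0.626056,
      "CA": 1.03157,
      "CC": 1.309026,
      "CG": 1.543797,
      "CT": 0.910627,
      "GA": 0.924855,
      "GC": 1.593597,
      "GG": 1.309026,
      "GT": 1.024455,
      "TA": 0.412628,
      "TC": 0.924855,
      "TG": 1.03157,
      "TT": 0.711427
    }
  },
  "cross_stacking": {
    "eps": 0.2,
    "a": 6.0,
    "r0": 0.545,
    "r_switch": 0.62,
    "r_cut": 0.85,
    "angle_c0": 0.0
  },
  "coaxial_stacking": {
    "enabled": false,
    "eps": 0.8,
    "a": 6.0,
    "r0": 0.42102687878474626,
    "r_switch": 0.55,
    "r_cut": 0.8,
    "angle_c0": -0.5
  },
  "excluded_volume": {
    "eps": 2.0,
    "sigma_backbone": 0.6,
    "sigma_base": 0.3,
    "sigma_back_base": 0.45
  },
  "misc": {
    "mass": 1.0,
    "inertia": 1.0,
    "pairing_fraction": 0.15
  }
}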