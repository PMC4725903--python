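{
  "schema_version": 1,
  "_comment": "Versioned physical defaults for MscL / lipid bilayer modeling. Units: lengths nm, energies kBT (room temperature), tension and moduli kBT/nm^2. Each entry carries a source note.",
  "bilayer": {
    "bending_rigidity": {
      "value": 14.0,
      "units": "kBT",
      "source": "typical experimental bending rigidity of phospholipid bilayers used throughout the MscL continuum-elasticity literature"
    },
    "thickness_modulus": {
      "value": 56.5,
      "units": "kBT/nm^2",
      "source": "effective thickness deformation (stretch) modulus Kt from micropipette area-stretch measurements"
    },
    "half_thickness": {
      "value": 1.6,
      "units": "nm",
      "source": "one-half the unperturbed hydrophobic thickness of E. coli-like bilayers (2a = 3.2 nm)"
    },
    "tension": {
      "value": 0.0,
      "units": "kBT/nm^2",
      "source": "default: tension-free bilayer unless a gating calculation sets tau > 0"
    }
  },
  "mscl": {
    "hydrophobic_thickness_closed": {
      "value": 3.8,
      "units": "nm",
      "source": "structural estimate of the closed-state MscL hydrophobic belt"
    },
    "hydrophobic_thickness_open": {
      "value": 2.5,
      "units": "nm",
      "source": "structural estimate of the open-state MscL hydrophobic belt (open MscL is thinner than the bilayer)"
    },
    "pentamer": {
      "closed": {
        "radius": 2.27,
        "undulation": 0.22,
        "source": "five-fold clover-leaf contour fitted to the M. tuberculosis pentameric structure (companion contour-modeling study)"
      },
      "open": {
        "radius": 3.49,
        "undulation": 0.11,
        "source": "clover-leaf contour for proposed open-state models; effective radius ~3.5 nm"
      }
    },
    "tetramer": {
      "closed": {
        "undulation": 0.22,
        "radius_matched_to": "pentamer.closed",
        "source": "tetragonal contour; undulation amplitude is NOT an independently measured value here - it is carried over from the companion clover-leaf contour modeling of MscL footprints; radius fixed by matching the pentamer cross-sectional area"
      },
      "open": {
        "undulation": 0.11,
        "radius_matched_to": "pentamer.open",
        "source": "same convention as closed tetramer; area matched to open pentamer"
      }
    }
  },
  "steric": {
    "edge_clearance": {
      "value": 0.5,
      "units": "nm",
      "source": "minimum edge-to-edge protein separation enforced by lipid size (roughly half a lipid diameter between hydrophobic belts)"
    }
  },
  "pair_table": {
    "d_step": 0.25,
    "omega_points_per_sector": 12,
    "d_cut": 12.0,
    "source": "tabulation resolutions; d_cut where thickness-mediated interactions effectively vanish (|E| <= 0.05 kBT)"
  },
  "meshing": {
    "contour_points_per_perimeter": 100,
    "far_field_factor": 4.0,
    "outer_clearance_lambdas": 10.0
  },
  "annealing": {
    "n_steps": 1000000,
    "t_start": 2.5,
    "t_end": 0.01,
    "unit_displacement": 0.5,
    "unit_rotation": 0.2,
    "source": "linear cooling in units of room temperature; the start temperature sits at roughly a quarter of the deepest pair-contact energy (~10 kBT), where contacts form but still break; much lower start temperatures freeze glassy aggregates; move sizes give ~50% acceptance near room temperature (diagnostic, not a constraint)"
  },
  "gating": {
    "tau_grid": [0.0, 0.625, 1.25, 1.875, 2.5],
    "units": "kBT/nm^2",
    "source": "tension scan up to ~2.5 kBT/nm^2 (~10 mN/m), the physiological MscL gating regime"
  }
}
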