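# Example pipeline configuration for `emligfit run --config pipeline.yaml`.
# Paths are resolved relative to the working directory.

# Candidate models of the protein-ligand complex (PDB or mmCIF), e.g. a
# batch of AI predictions. Order is preserved in the ranking table.
candidate_paths:
  - fixture/cand0.pdb
  - fixture/cand1.pdb
  - fixture/cand2.pdb
  - fixture/cand3.pdb
  - fixture/cand4.pdb

# Target cryo-EM map (MRC/CCP4, mode 2).
map_path: fixture/target_map.mrc

# Optional deposited structure; enables the accuracy columns of the report.
# Never used during fitting, only for evaluation.
ground_truth_path: fixture/ground_truth.pdb

output_dir: out

# Nominal map resolution in Angstrom; sets the Gaussian width of simulated
# densities (sigma = resolution / 2.355).
resolution: 3.2

# Ligand residue name, or "auto" for the largest non-water hetero residue.
ligand_name: LIG

# Pocket = protein residues with any atom within this many Angstrom of the
# ligand.
pocket_cutoff: 4.0

# Rigid-fit restarts per candidate during ranking; 1 suffices for models
# that are already roughly placed in the map.
rigid_restarts: 1

# How the "fitted" values in the report are reduced from the run:
# "final" (last frame) or "last20" (mean over the final 20 saved frames).
reducer: final

# Master seed for every stochastic stage (thermostat noise, restarts).
seed: 0

# Flexible-fitting engine. Omitted fields keep their defaults.
fit:
  timestep_fs: 2.0
  temperature: 310.0          # K
  friction: 1.0               # 1/ps
  force_constant_k: 1000.0    # kJ/mol, initial density-force scale
  density_force_interval: 2   # recompute the map force every N steps
  duration_ps: 50.0
  force_cap: 10000.0          # kJ/mol/A per atom; >1% over => graceful stop
  trace_interval_fs: 50.0
  frame_interval_ps: 1.0
  adaptive:                   # adaptive force scaling
    enabled: true
    check_interval: 50        # density-force applications per decision
    cc_epsilon: 1.0e-4        # improvement below this counts as a stall
    growth_factor: 1.05
    k_max: 1.0e5
  pre_relax:                  # restrained minimisation before dynamics
    enabled: true
    minimize_steps: 5000
    backbone_restraint: 400.0   # kJ/mol/nm^2 on protein N/CA/C
    sidechain_restraint: 40.0   # kJ/mol/nm^2 on everything else
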