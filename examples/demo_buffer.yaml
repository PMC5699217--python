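# Shipped demo: coarse G3.5 dendrimer (-64 e) with 32 Na+ and 16 Ca2+ in
# the ~460,000 A^3 buffer box; three replicate Brownian-dynamics runs.
# Run with:  chelax run --config examples/demo_buffer.yaml --out scratch/demo
name: g35-buffer-demo
solute:
  kind: dendrimer
  generation: 3.5
  core_multiplicity: 4
  sphere_radius: 15.0
  site_radius: 2.0
box_edges: [77.1817, 77.1817, 77.1817]
species:
  - {name: Na, valence: 1, count: 32}
  - {name: Ca, valence: 2, count: 16}
neutralizer: Cl
shell: 8.0
threshold: 3.0
replicates: 3
seeds: [1, 2, 3]
bd:
  n_steps: 60000
  timestep: 0.01
  save_interval: 30
  screening_length: 8.0
  lj_epsilon: 1.0
  lj_sigma: 3.0
rdf:
  bin_width: 0.25
  r_max: 35.0
  reference: com
protocol:
  n_steps: 15000000
  timestep_fs: 2.0
  stated_duration_ns: 30.0
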