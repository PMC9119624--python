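# polyphase

Coarse-grained simulation and analysis of self-associating semi-flexible
polymers whose assembly is driven by the interplay of a strong, *specific*
interaction patch and weak, promiscuous *non-specific* interactions.

Chains are bead–spring polymers (default: 80 beads, 7-bead central
specific patch) with

* harmonic stretching `E = k_s (r − r0)²` (literal form, no ½ prefactor),
* bending `E = κ (1 − cos θ)` over consecutive bonds,
* truncated (unshifted) Lennard-Jones between all non-bonded beads under
  cubic periodic boundaries — attractive pairs cut at 2.5 σ,
  repulsive-only pairs at 2^(1/6) σ.

Pair depths are given in units of k_B T at a reference temperature
(defaults: ε_sp = 1.2, ε_ns = 0.5 at 310 K) and converted once to
kcal/mol. Dynamics use a BAOAB-discretized Langevin (NVT) integrator
(dt = 30 fs, damping 1.2 ps, bead mass 110 Da) with a Verlet neighbor
list; an optional parallel-tempering layer (default ladder 309–401 K in
4 K steps, configuration swaps with Boltzmann acceptance) produces
free-energy profiles over specific-contact order parameters.

The analysis stage implements the full set of condensate order
parameters: per-bead specific/non-specific inter-chain contact counts at
a 2.5 σ cutoff, chain cluster decomposition (N_lc), radii of gyration of
the specific beads (raw and divided by N_lc), 3 Å radial shell
fraction/density profiles, and dwell/maturation kinetics for dimers.

## Layout

| module | contents |
| --- | --- |
| `polyphase.model` | bead roles, interaction tables, engine parameters, units |
| `polyphase.builder` | role sequences, boxes from concentration, seeded initial configurations, scripted fixture trajectories |
| `polyphase.engine` | energies/forces and the BAOAB Langevin integrator (`polyphase._kernels`: numba hot loops) |
| `polyphase.remd` | temperature ladders, Metropolis swaps, free-energy profiles |
| `polyphase.analysis` | contacts, clusters, Rg, shells, dwell/maturation times |
| `polyphase.config` / `polyphase.io` / `polyphase.cli` | YAML configs, XYZ / LAMMPS-dump / npz trajectory IO, command line |

## CLI

```sh
polyphase build  --config cfg.yaml --out initial.xyz
polyphase run    --config cfg.yaml --steps 100000 --seed 1 --out traj.lammpstrj
polyphase remd   --config cfg.yaml --tmin 309 --tmax 401 --dt-ladder 4 --out-dir remd/
polyphase analyze kinetics --traj traj.lammpstrj --out kinetics.tsv
polyphase sweep  --config cfg.yaml --eps-ns 0.1,0.5,1.0 --eps-sp 1.2 --out sweep.tsv
```

A minimal config:

```yaml
system:
  n_chains: 2
  chain_length: 80
  patch_len: 7
  box_edge: 150.0
interactions:
  eps_sp: 1.2
  eps_ns: 0.5
run:
  n_steps: 100000
  report_every: 1000
  seed: 1
```

Every run archives its config next to the outputs; identical configs and
seeds give identical outputs.

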