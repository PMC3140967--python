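# inmkit

Elastic-network **instantaneous-normal-mode (INM)** analysis of protein
conformational switching, plus the ensemble observables that usually
accompany it: Schlitter configurational entropy by region, solvent
accessible surface area (SASA) profiles, and backbone-dihedral statistics.

The core idea: every structure (crystal reference or trajectory snapshot)
is treated as the reference geometry of its own Tirion elastic network —
harmonic springs between all CA pairs within a distance cutoff (default
13 Å). Diagonalizing the network Hessian gives low-frequency normal modes;
each of the *n* lowest query modes (default 2) is matched to the template
mode of maximal absolute overlap, and the similarity

```
S = Σ ω_m(i) |⟨v_i, v_m(i)⟩| / Σ ω_m(i)   ∈ [0, 1]
```

(weights = matched template-mode frequencies) scores how closely the two
conformations share a collective-motion signature. Scanning a trajectory
against "open" and "closed" templates yields a similarity trace, per-frame
state labels (thresholds 0.95 / 0.85, dwell filter), transition counts and
percentage tables.

## Layout

| module                | contents |
|-----------------------|----------|
| `inmkit.structures`   | PDB I/O (single and multi-model), atom selection, residue mapping (explicit / offset / built-in global aligner), Kabsch superposition, RMSD traces |
| `inmkit.enm`          | Tirion networks, analytic Hessian, normal modes |
| `inmkit.similarity`   | mode matching, INM similarity, trajectory traces, state calling, transition tables |
| `inmkit.observables`  | covariance building, Schlitter entropy (per region, block stds), Shrake–Rupley SASA, φ/ψ dihedrals and densities |
| `inmkit.synthetic`    | hinge-protein conformers, dwell/switch trajectories, Gaussian ensembles with analytic entropy truth |
| `inmkit.config` / `inmkit.cli` | TOML run config, end-to-end pipeline, command-line tools |

## CLI

```sh
# synthetic fixtures
inm-synth hinge --state open --out open.pdb
inm-synth hinge --state closed --out closed.pdb
inm-synth trajectory --open open.pdb --closed closed.pdb \
    --n-frames 200 --switch-frame 50 --noise 0.3 --seed 1 --out traj.pdb

# similarity trace, state calls, transition table
inm-trace --traj traj.pdb --open open.pdb --closed closed.pdb \
    --n-modes 2 --cutoff 13 --out trace.tsv
inm-classify --trace trace.tsv --high 0.95 --low 0.85 --dwell 5 \
    --out calls/hinge__open__1.json
inm-table --calls calls/

# ensemble observables
inm-entropy --traj traj.pdb --regions regions.toml --blocks 3 \
    --temp 300 --out entropy.tsv
inm-sasa --traj traj.pdb --range 1-30 --probe 1.4 --out sasa.tsv
inm-dihedrals --traj traj.pdb --residues 5,6,7 --bins 72 --out dih.tsv
```

`regions.toml` maps names to inclusive residue intervals, e.g.
`cleft = [[27, 175]]`. A whole pipeline can also be driven from one TOML
file via `inm run --config run.toml --outdir out/`.

Trajectories are multi-model PDB as the guaranteed baseline; other MD
formats are read through MDAnalysis when it is installed.

## Conventions

- Å everywhere; residue ids are author-assigned PDB numbers; intervals are
  inclusive on both ends.
- ENM nodes are CA-only by default and unit-mass, so mode frequencies are
  in arbitrary units (they cancel in the similarity weighting).
- Eigenvector signs are solver-dependent: all overlap consumers use
  absolute values. `S(a,b)` need not equal `S(b,a)`; the convention is
  query = snapshot, template = reference.
- Schlitter entropy is reported molar (`J/mol/K` default, `kJ/mol/K`
  selectable) and is an upper bound on the configurational entropy.
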