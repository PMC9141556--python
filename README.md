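# nbens — nanobody paratope ensemble analysis

`nbens` is a toolkit for characterizing the conformational ensembles of
nanobody paratopes and cross-validating them against NMR observables. It
implements, as small composable modules with analytically testable toy
counterparts:

- **`structure_io`** — multi-model PDB ensembles, CYANA `.upl` upper-limit
  restraint lists (with pseudoatom expansion), a plain-text coordinate-table
  trajectory format, Kabsch superposition and backbone phi/psi torsions.
- **`synthetic_data`** — generators with exact ground truth: unit bond
  vectors diffusing in a cone (closed-form S²), two-state hopping torsion
  loops (known labels), a 1-D Langevin particle in an analytic double well
  (known free energy), and fluctuating bead chains (exact distance records).
- **`cv_landscape`** — (sin, cos) torsion featurization, linear sine/cosine
  collective variables, reversible (symmetrized) tICA, relative free-energy
  surfaces over (tIC1, tIC2), and average-linkage RMSD clustering with a
  distance cutoff.
- **`metadynamics`** — well-tempered metadynamics on toy systems
  (tempered Gaussian hills, default schedule 10 kJ/mol height, 0.3 rad
  width, deposition every 1000 steps, bias factor 10, 300 K), free-energy
  reconstruction, and Metropolis bias-exchange moves between replicas.
- **`nmr_observables`** — NOE effective distances with r⁻⁶ averaging over
  frames and pseudoatom proton pairs, violation reports under both an
  ensemble-averaged and a per-model counting convention, and Lipari–Szabo
  S² via second moments or the P2 correlation plateau.
- **`restrained_dynamics`** — bead-chain Langevin dynamics (BAOAB) with
  flat-bottom upper-limit restraints, either instantaneous or driven by an
  exponential-memory time average (default τ = 100 ps, r⁻³ averaging).
- **`ensemble_stats`** — ensemble precision RMSD (iterative superposition
  to the mean), Cα accuracy versus a reference structure, four-class
  Ramachandran classification from shipped region grids, van der Waals
  close contacts, and a combined refinement-statistics report.

## Command line

The `nbens` entry point wraps the library:

```sh
nbens synth cone --seed 1 --out cone            # synthetic data + ground truth
nbens restraints --upl limits.upl --summary     # parse/summarize a .upl file
nbens tica --torsions psi.txt --lag 10 --out t  # tICA + free-energy surface
nbens metad --steps 200000 --out mtd            # well-tempered metadynamics toy
nbens noe --pdb ens.pdb --upl limits.upl --threshold 0.2 --out noe.tsv
nbens s2 --pdb ens.pdb --out s2.tsv             # backbone amide S²
nbens restrain --upl limits.upl --mode tavg --tau 100 --steps 10000 --out run
nbens report --ensemble ens.pdb --reference ref.pdb --upl limits.upl \
      --range 3:113 --out table.tsv             # quality statistics table
```

All outputs are plain text (coordinate tables, HILLS-style hill logs, TSV
reports).

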