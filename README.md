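# clasp-sites

Catalytic active-site prediction for protein structures by **spatial
motif congruence** plus **electrostatic potential-difference (PD)
conformity**.

Structure-based annotation tools that match 3D side-chain motifs (a
Ser–His–Asp triad, a β-lactamase Ser–Lys–Ser–Lys tetrad, …) produce many
spatially plausible false positives.  This package implements the
observation that, within an enzyme family, the electrostatic potential
difference between each pair of catalytic reactive atoms falls in a
narrow band (kT/e units, from a finite-difference linearized
Poisson–Boltzmann solution), and uses conformity to that band to prune
and re-rank geometric matches.  It is aimed at structural
bioinformaticians screening structures of unknown or promiscuous
function against libraries of active-site templates, e.g. Catalytic Site
Atlas (CSA) derived motifs.

A match of an n-site motif is scored

    S = w_d Σᵢ |d_q,i − d_ref,i| / d_ref,i
      + w_p Σᵢ |P_q,i − P_ref,i| / max(|P_ref,i|, P_floor)

over the n(n−1)/2 reactive-atom pairs (PD pairs where both query and
reference are inside a near-zero ignore band are skipped).  Lower is
better; a motif probed in its own reference structure scores exactly 0.
See `docs/methods.md` for the model, solver, parameters and limitations.

## Worked example

Build a motif from a structure with a planted catalytic triad, then
score the same structure against it (the library API mirrors the CLI):

```python
import clasp
from clasp import fixtures as fx
from clasp.motif_library import build_motif
from clasp.scoring import best_match

text = fx.trypsin_triad_structure()          # toy PDB, Ser-His-Asp planted
s = clasp.read_pdb(text)
grid = clasp.solve_potential(clasp.assign_parameters(s),
                             clasp.GridParams(spacing=0.8, padding=8.0))
motif = build_motif(s, grid, ["A:1", "A:2", "A:3"],
                    ["Sergrp", "Hisgrp", "Aspgrp"])
print("d_ref:", motif.d_ref.round(2))
top, _ = best_match(s, motif, grid)
print("best:", top.label(), "S =", top.score)
```

prints

```
d_ref: [3.3 7.8 5.5]
best: SER1+HIS2+ASP3 S = 0.0
```

`d_ref` are the pairwise reactive-atom distances (Å) of the triad —
Ser OG–His NE2 3.3 Å, Ser OG–Asp OD1 7.8 Å, His NE2–Asp OD1 5.5 Å — and
the zero score is the self-match identity: no distance deviation and no
PD deviation.

The same flow from the shell:

```sh
clasp fixtures make --kind motif --seed 0 --out fx/
clasp motif build fx/triad.pdb --residues A:1,A:2,A:3 \
      --groups Sergrp,Hisgrp,Aspgrp --spacing 0.8 --out fx/triad.motif
clasp score fx/triad.pdb --motif fx/triad.motif --spacing 0.8
# best: SER1+HIS2+ASP3  S=0.000 (D=0.000, P=0.000)
```

Other subcommands: `clasp search` (TSV of congruent tuples), `clasp
scan` (rank a motif library against one structure), `clasp grid` (solve
and export an OpenDX potential grid, internal or external backend),
`clasp eval` (sensitivity/specificity/FPR and ROC from labeled scores),
`clasp motif from-csa` (filter a CSA listing into motif specs).

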