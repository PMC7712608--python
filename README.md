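# rdcfold

Protein backbone structure determination from residual dipolar couplings
(RDCs) by two-stage torsion-space fragment assembly.

RDCs are orientation-dependent NMR observables: under weak alignment, the
coupling between two nuclei reports the average orientation of their
internuclear vector through

    D_ij = Dmax · v_ij · S · v_ij^T ,        Dmax = −μ0 γ_i γ_j h / (2π r)^3 ,

where `S` is the medium's 3×3 symmetric traceless Saupe order tensor.
Given a set of couplings from one or more alignment media, `rdcfold`
searches backbone torsion space for the conformation that best explains
them, scoring every candidate by the RMS deviation (Hz) between measured
couplings and couplings back-calculated through per-medium best-fit
tensors:

    Fitness = sqrt( Σ_m Σ_i (D_mi − D′_mi)² / (M·N) )

The search runs in two stages. **Stage I** enumerates the discretized
(φ, ψ) grid at every junction between adjoining peptide planes, filters it
by Ramachandran class, optionally intersects it with data-mined dihedral
restraints (predicted angles ± 25° in 5° steps), and ranks candidates by
local RDC fitness.  **Stage II** assembles the chain peptide plane by
peptide plane with a beam search: each step crosses the beam with the next
junction's candidates, scores all children, prunes with *dynamic
decimation* — keep children scoring below `best·(1 + n %)`, so the pool
adapts to data quality instead of obeying a fixed absolute threshold —
and carries the best `depth` fragments forward.

The package is aimed at NMR spectroscopists and methods developers: it
reads RDC restraints in NEF (NMR Exchange Format, any backbone atom-pair
combination) and the legacy six-column per-residue table, mines φ/ψ
restraints from a local PDB corpus, and ships a simulator so the whole
pipeline is testable without downloading anything.

## Worked example

Simulate a noisy two-media dataset from the built-in 15-residue helix
fixture, fold it back, and compare with the generating structure:

```sh
$ rdcfold simulate --fixture helix15 --noise 1 --seed 7 -o data
simulated 176 couplings (6 types, E=1.0 Hz) into data

$ cat > run.ini <<'CFG'
[input]
sequence = data/helix15.seq
rdc_files = data/helix15.nef
format = nef

[search]
depth = 100
decimation = dynamic
tolerance = 50        ; percent band above the running best score
grid_step = 5
seed = 7

[output]
out_file = run.out
pdb_file = final.pdb
CFG

$ rdcfold stage2 run.ini
final fitness 0.5541 Hz over 176 couplings in 2 media
trace: run.out
structure: final.pdb

$ python - <<'PY'
from rdcfold.geometry import read_pdb, bb_rmsd
print(f"bb-rmsd to truth: "
      f"{bb_rmsd(read_pdb('final.pdb'), read_pdb('data/helix15_truth.pdb')):.3f} A")
PY
bb-rmsd to truth: 0.027 A
```

Reading the numbers: ±1 Hz uniform noise has an RMS of 1/√3 ≈ 0.577 Hz,
so a final fitness of 0.55 Hz means the structure explains the couplings
down to the noise floor — the search cannot and should not do better.  A
final fitness far above E/√3 is the standard sign that the search lost
the true branch.  The 0.03 Å backbone RMSD confirms the fold recovered
the generating helix.

Other subcommands: `rdcfold stage1` (write the per-junction candidate
angle files), `rdcfold pdbgen '<phi:psi;...>' <SEQ>` (build a PDB from
torsions, or replay any rank of a `.out` trace), `rdcfold convert`
(legacy table → NEF), `rdcfold mine` (predict dihedral restraints from a
local PDB corpus).  Library API: see `rdcfold/__init__.py` and
`docs/methods.md`.

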