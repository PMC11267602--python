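# csmeasure

Continuous symmetry and chirality measures for molecular structures.

Molecules are rarely perfectly symmetric: thermal motion, substitution,
guest binding, crystal packing or conformational change distort the ideal
geometry without destroying it.  `csmeasure` replaces the binary
symmetric/asymmetric classification by a continuous one.  For a structure
with centered coordinates P₁…P_N and a target cyclic point group *G*
(*C*ₛ, *C*ᵢ, *C*ₙ, *S*ₙ), it computes the **continuous symmetry measure**

    S(G) = 100 · min Σᵢ ‖Pᵢ − Qᵢ‖² / Σᵢ ‖Pᵢ‖²

minimized over every structure Q that is exactly *G*-symmetric under an
admissible atom permutation.  S(G) = 0 means the symmetry is already
present; 100 is the maximal-distortion reference.  Along with the value,
the package reports the optimal atom permutation, the direction of the
symmetry element, and the coordinates of the nearest symmetric structure.
The **continuous chirality measure** (group label `ch`) is the minimum of
S over the achiral groups S1 (= Cs), S2 (= Ci), S4, S6, …

Three calculation approaches cover different molecule sizes:

- **exact** — enumerate all admissible permutations (optionally only the
  bond-graph automorphisms with `--keep-structure`), with an analytic
  axis optimum per permutation;
- **approx** — for large structures, alternate Hungarian (or greedy)
  assignment of atoms to their rotated images with analytic axis
  refinement, from several start directions;
- **trivial** — score the identity (or, for protein homomers,
  sequence-dictated) permutation without any search.

Protein homo-oligomers get a dedicated layer: sequence-based atom
equivalence, chain/residue/backbone selection, and a combined
chain-and-atom permutation search.

## Command-line usage

    csmeasure exact  <input> <group> <outdir> [flags]
    csmeasure approx <input> <group> <outdir> [flags]
    csmeasure trivial <input> <group> <outdir>
    csmeasure comfile <input> <outdir> --cmd cmd.txt

Inputs may be xyz, pdb, mol/sdf, the internal csm dialect, a concatenated
multi-model file, or a directory of files.  Group labels are
case-insensitive: `cs`, `ci`, `c2`, `c3`, …, `s4`, `s6`, …, `ch`.
Frequently used flags: `--keep-structure`, `--use-perm FILE`,
`--ignore-sym`, `--remove-hy`, `--select-atoms LIST`, `--select-mols
LIST`, `--connect FILE`, `--infer-bonds`, `--greedy`, `--fibonacci N`,
`--sn-max N`, `--simple`, and the protein flags `--use-sequence`,
`--use-chains`, `--select-chains`, `--select-res`, `--use-backbone`.

## Worked example

Build a slightly distorted three-fold ring (two orbits of a C3 rotation,
Gaussian noise of 0.05 Å) and measure its residual C3 symmetry:

```python
from csmeasure import PointGroup, write_structure
from csmeasure.fixtures import make_symmetric, perturb

mol = perturb(make_symmetric(PointGroup.parse("c3"), n_orbits=2, seed=1),
              0.05, seed=2)
write_structure(mol, "xyz", "ring.xyz")
```

    $ csmeasure exact ring.xyz c3 out
    model 1: 2 equivalence classes (sizes 3, 3); 9 permutations examined

    $ cat out/csm.txt
    group: C3
    algorithm: exact
    value: 0.080134

    $ cat out/permutation.txt
    2 3 1 5 6 4

    $ cat out/directional.txt
    0.00832478 -0.00236441 0.99996255

S(C3) = 0.0801: the noise displaced the structure less than a tenth of a
percent of its size from perfect three-fold symmetry.  The permutation
file lists the 1-based image of each atom under the symmetry operation —
here the two 3-cycles that rotate each orbit — and `directional.txt` is
the unit axis of the recovered symmetry element, within half a degree of
the z-axis it was built around.  The output directory also contains the
centered input (`initial_coordinates.xyz`) and the nearest exactly
C3-symmetric structure (`resulting_symmetric_coordinates.xyz`); running
the same command on the latter returns 0.000000.

The chirality measure of the same molecule:

    $ csmeasure exact ring.xyz ch --sn-max 6 --simple
    csmeasure 0.1.0
    2 equivalence classes (sizes 3, 3)
    S(ch (min at Cs)) = 0.755808  [exact+ccm]

The structure is 0.76 units from its nearest achiral geometry, attained
through a mirror plane (Cs).

The same computations are available as a library
(`exact_csm`, `approx_csm`, `ccm`, `chain_permutation_search`, …); see
`docs/methods.md` for the model, the algorithms and their numerical
conventions.

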