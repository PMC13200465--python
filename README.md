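# lignoforge

Diversity-oriented virtual synthesis of lignin oligomer libraries, with the
chemical-space metrics and high-resolution mass-spectrometry (HRMS) suspect
annotation built on top of them.

Lignin is an aromatic plant biopolymer of phenylpropanoid (C6–C3) residues
joined by a handful of named linkages (β-O-4, β-β, β-5, 5-5, …). Native and
process-modified lignins are so isomeric that stochastic polymerization
simulators cover only a sliver of the plausible structures. `lignoforge`
takes the combinatorial route instead: it enumerates *every* linear oligomer
reachable from a user-editable table of monomer residues and linkage rules,
up to a chosen degree of polymerisation (DP). The resulting exhaustive
libraries have hard chemical-space boundaries, which makes them useful for
validating DP classifiers and for deriving suspect lists for HRMS
annotation, with honest isomer counts behind every candidate mass.

Intended users: analytical chemists and cheminformaticians working on lignin
depolymerisation, lignin-derived chemicals, or non-target screening of
complex aromatic mixtures.

## What it computes

**Nomenclature.** Residues carry descriptive six-letter symbols built from
three two-letter moiety codes — substituted benzene ring, side chain,
side-chain substituent. `GUmeal` (guaiacol–methylene–aldehyde) is the
vanillin residue; divanillin is written `GUmeal[5-5]GUmeal`, with linkages
as vertex-to-vertex tokens (`[b-O-4]`, `[5-5]`, …; `O` marks an ether
bridge). A linear sequence read backwards denotes the same molecule, so
every sequence has a *mirror duplicate*; the canonical identifier — the
alphabetically sorted pair of forward and reversed serializations — is
invariant under reversal and drives duplicate removal.

**The engine.** Growth is table arithmetic, not graph chemistry. Each
n-mer row carries its molecular formula and the boolean reactivity state of
its endgroup (free 4-OH? open C5? conjugated vinyl? side chain intact?).
A linkage rule filters both tables by its prerequisites, takes the full
cross product, adds formulas together with a signed correction term
(e.g. +O for β-O-4, −2H for β-β, −C3H4 for β-1), and derives the new
endgroup state from the incoming monomer minus the consumed moieties.
Mirror twins are retained as substrates — `AAB` and `BAA` grow into
different (n+1)-mers — and collapsed per degree in the output view.

**Metrics and annotation.** From the formulas: exact masses, ring-double-bond
equivalents (RDBE = 1 + Σ nᵢ(vᵢ−2)/2), Kendrick mass defects over seven
recurring lignin fragments (CO, CHO, CH₂O, CH₃O, CO₂, CHO₂, C₅H₅O), O/C
ratios, PCA with 95% confidence ellipses, and RDBE-window DP classification.
Libraries collapse to suspect lists (one row per unique exact mass, with
isomer count); feature m/z values match against them within a ppm or mDa
tolerance, and isomer counts map to annotation-confidence sublevels
(defaults: 1 candidate → 3a, 2–20 → 3b, >20 → 3c).

**SMILES without molecular graphs.** Sequence names translate directly to
SMILES through static snippet dictionaries keyed by each residue's backbone
connectivity class, with ring-closure indices allocated on the fly. Every
emitted structure is checked by a formula round-trip.

## Worked example

```python
from lignoforge import (
    grow_library, default_linkage_rules, dp_rdbe_table,
    translate_sequence_to_smiles, build_suspect_list,
)
from lignoforge.fixtures import conventional_monolignols
from lignoforge.registry import default_residue_table

lib = grow_library(conventional_monolignols(), default_linkage_rules(), 4)
print({d: len(lib.frame(d)) for d in lib.degrees})
# {1: 3, 2: 48, 3: 640, 4: 9303}

print(dp_rdbe_table(lib).as_frame())
#  degree  rdbe_min  rdbe_max  count
#       1       5.0       5.0      3
#       2       8.0      10.0     48
#       3      12.0      15.0    640
#       4      16.0      20.0   9303

r = translate_sequence_to_smiles("GUmeal[5-5]GUmeal", default_residue_table())
print(r.smiles)   # C(c1cc(OC)c(O)c2c1)=O.C(c1cc(OC)c(O)c2c1)=O  (divanillin, C16H14O6)

print(len(build_suspect_list(lib)))   # 110 unique masses behind 9994 oligomers
```

The library here is the "conventional" benchmark: H/G/S monolignol residues
(p-coumaryl, coniferyl, sinapyl alcohol) under the seven conventional
linkages. Its per-degree RDBE windows — 8–10 for dimers, 12–15 for trimers,
16–20 for tetramers (and 20–25, 24–30 continuing to hexamers) — are the
basis of RDBE-based DP classification: an RDBE of 9 can only be a dimer,
while 20 is the first ambiguous value (tetramer or pentamer). The 48 unique
dimers compress to 15 exact masses with a mean of 3.2 isomers per mass;
isomer counts grow by roughly an order of magnitude per degree, which is
why suspect-list matches report them.

The same workflow is available from a shell:

```bash
lignoforge grow --select HYpeol,GUpeol,SYpeol --max-degree 4 --out lib/
lignoforge smiles  --library lib/
lignoforge suspect --library lib/ --out suspects.csv
lignoforge match   --features features.csv --suspects suspects.csv --tol-ppm 3 --out matches.csv
lignoforge space   --library lib/ --out space.csv --plot space.png
lignoforge qc      # validate the packaged registry and rules
```

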