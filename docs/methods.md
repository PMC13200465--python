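# Methods

## Model

`lignoforge` models lignin oligomers as *linear sequences of monomer
residues* joined by named linkages. A residue is what is actually found in
the chain (coniferyl-alcohol residue, vanillin residue, …), not the monomer
that hypothetically formed it; this keeps the nomenclature descriptive for
process-modified lignins. Branching is not modelled: every oligomer has
exactly two ends, and growth always happens at one designated endgroup.
Because the other end is supplied by mirror retention (below), single-ended
extension still enumerates every linear constitution.

Chemistry is tracked at two levels only:

1. **Element counts.** Each residue carries a molecular formula; each
   linkage carries a signed correction term (atoms gained or lost in the
   coupling). Exact masses, RDBE and all downstream metrics derive from
   these counts. No molecular graph is ever built by the engine.
2. **Boolean reactivity state.** Four flags describe the moieties a residue
   can still offer: `vinyl_available` (conjugated side-chain double bond,
   needed for β-couplings), `phenol4_available` (free 4-OH),
   `ring5_open` (unsubstituted C5; always false for syringyl residues,
   whose 5-OMe blocks it), `sidechain_intact` (C1 side chain present,
   required of a β-1 acceptor). A fifth state, `alive`, marks whether the
   endgroup can react at all.

This is deliberately coarse: everything between the endgroup and the first
residue is a black box during growth, which is what makes the cross-product
formulation exact and fast.

## Growth, mirrors, and deduplication

One growth step under one linkage rule and direction:
filter the n-mer table by the endgroup-side prerequisites and the monomer
table by the monomer-side prerequisites; form the full cross product;
concatenate names with the oriented linkage token; add formulas plus the
correction term (any negative element count is an error in the rule, not
data to clamp); set the new endgroup flags to the monomer's flags minus the
consumed moieties, `alive=false` if the rule is a terminator. Asymmetric
rules run in both directions (the endgroup may play either vertex);
symmetric rules run once.

A linear sequence and its reversal (with every token's vertices swapped)
denote the same molecule. These mirror twins cannot be discarded during
growth — `AAB` and `BAA` extend into different sequences — so substrate
tables keep them, and each degree's *output view* is deduplicated only once
that degree has produced the next one. Deduplication keys on the canonical
identifier: the alphabetically sorted pair of forward and mirror
serializations joined by `|`. The sorted *pair* (rather than just the
minimum) is kept for debuggability; both are reversal-invariant and
injective on reversal classes, which the test suite verifies exhaustively
on small alphabets. Ties resolve to the row whose forward name is the
lexicographic minimum, giving deterministic output ordering. Incremental
forward/reverse name columns make the identifier a vectorized string
operation; growth cost is linear in product rows. A configurable substrate
row cap (default 5·10⁷, roughly what fits in tens of GB at ~300 bytes per
row) fails cleanly instead of exhausting memory.

## Default linkage stoichiometry

The packaged rules fix prerequisites and correction terms so that every
dimer reproduces its literature model compound; all of it is plain CSV and
overridable. Monolignol residues all have RDBE 5, so each linkage adds a
fixed RDBE increment (last column):

| linkage | bridge | prerequisites (endgroup / monomer side) | consumed | Δ formula | ΔRDBE |
|---|---|---|---|---|---|
| β-O-4 | ether | vinyl / 4-OH | vinyl / 4-OH | +O | +4 |
| α-O-4 | ether | vinyl / 4-OH | vinyl / 4-OH | +O | +4 |
| β-β | C–C | vinyl / vinyl | both vinyls | −2H | +5 |
| β-5 | C–C | vinyl / C5+4-OH | vinyl; C5+4-OH | −2H | +5 |
| 5-5 | C–C | C5 / C5 | both C5 | −2H | +5 |
| 5-O-4 | ether | C5 / 4-OH | C5; 4-OH | −2H | +5 |
| β-1 | C–C | vinyl / side chain | vinyl; side chain+vinyl | −C3H4 | +3 |

Checks: β-O-4 on two coniferyl residues gives C20H24O7 (guaiacylglycerol-
β-coniferyl ether, RDBE 9); β-β gives C20H22O6 (pinoresinol, RDBE 10); β-5
gives C20H22O6 (dehydrodiconiferyl alcohol); β-1 gives C17H20O6 (the
1,2-diarylpropane-1,3-diol, RDBE 8).

β-1 is implemented as a **terminator** (the acceptor loses its side chain
and the new endgroup is dead) and runs forward only. This both matches the
displacement chemistry — the acceptor's propanoid chain leaves — and is
what makes the benchmark RDBE minima come out right: with at most one β-1
per oligomer the degree-d minimum is one β-1 plus (d−2) ether linkages,
5 + 3 + 4(d−2) = 4d, i.e. 8/12/16/20/24 for dimers–hexamers, while the
maximum is all-C–C coupling at 5d. Allowing β-1 mid-chain would push
minima below these windows.

The benchmark RDBE ranges can be computed two ways: on the fully grown
library, or on the per-degree sets of distinct (formula, endgroup-state)
pairs reached by the same transition rules. Since extension eligibility
depends only on the endgroup state, both routes reach exactly the same
formulas; the state route runs in milliseconds. The acceptance script uses
the state route at degree 6; the tests assert route agreement on grown
libraries to degree 4 (the degree-6 substrate table is ~10⁷ rows, which is
real minutes and memory for no extra information).

Absolute library sizes are *reported, not asserted*: they are logged per
degree by `grow_library` and echoed by the CLI. Published counts for
comparable configurations (e.g. millions of unique oligomers for an H/G/S
hexamer library) depend on the exact residue database and
filtration/correction tables used, which vary between deployments; RDBE
extrema are robust to those details under the stoichiometry above, sizes
are not.

## SMILES translation

Sequence names translate to SMILES without a graph intermediate. The
linkage vertices pin down the intra-residue connectivity too, so each
residue reduces to a *backbone class*: how its side chain participates
(free allyl; β-O-4/α-O-4/β-1 donor; resinol half; phenylcoumaran donor) and
which ring sites are used (O4 as ether oxygen, C5 as coupling site, C1 when
the side chain was displaced). Side-chain classes map to snippet templates
in `chain_snippets.csv`; the aromatic ring is assembled from the residue's
methoxylation pattern plus the used sites. Vertex labels alone do not
determine local chemistry — β-5 engages the acceptor's C5 *and* its O4 in
the coumaran ring, unlike 5-5 — so classes are keyed by linkage type and
side, not bare vertices.

Each residue becomes its own dot-separated SMILES component; *all*
inter-residue bonds (three for a resinol, two for a coumaran) are emitted as
ring-closure indices shared across components. That keeps every snippet
independently balanced and reduces ring bookkeeping to one linear pass:
indices allocate sequentially, are recycled at closure, and switch to
`%nn` above nine concurrently open bonds. No stereodescriptors are emitted —
the engine enumerates constitutions, and β-β/β-5 stereocenters would imply
precision the model does not have.

The shipped dictionaries cover the canonical H/G/S residues with
alcohol/aldehyde/acid side-chain substituents, the vanillin-type residue and
the seven default linkages, with one deliberate gap: resinol (β-β) snippets
exist only for γ-alcohol side chains, because the bicyclization consumes the
γ-OH — an aldehyde or acid γ-carbon cannot form that ring, and pretending
otherwise would emit formula-inconsistent structures. Such sequences raise
a missing-key error, and `snippet_coverage_report` lists every reachable
class a registry demands that the tables lack.

Correctness is defined observationally: every emitted SMILES must be
syntactically valid and reproduce the record's tracked formula. The
round-trip counter (explicit atoms + implicit hydrogens under organic-subset
valences, aromatic carbon contributing one fewer) is part of the package;
the test suite additionally checks every emitted structure against RDKit as
an independent parser, at 100% agreement over the full conventional library
to degree 3.

## Mass-spectrometric conventions

* Monoisotopic masses from a packaged table (C 12 exactly, H 1.00782503,
  O 15.99491462, N 14.00307401, S 31.97207117) so results are bit-stable.
* KMD = round(KM) − KM with banker's rounding by default (configurable to
  floor/ceiling; conventions differ between groups). Seven Kendrick bases
  are shipped; usage in the field sometimes drops one of them, so the
  selection is an argument, not a constant.
* RDBE uses the generalized valence formula; O and S contribute zero,
  matching conventional CHO-compound usage, and half-integer values (radical
  formulas) are returned rather than rounded.
* Suspect keys group exact masses at 4 decimals (~0.1 mDa), finer than any
  realistic matching tolerance, so grouping never hides a match. Isomer
  counts are per rounded neutral mass (not per formula; distinct formulas
  almost never collide at 4 decimals in this mass range).
* Default matching tolerance is ±3 ppm, switchable to mDa. Instrument-side
  filters (isotopic fit / mSigma) are upstream concerns; extra feature
  columns pass through untouched.
* Adduct arithmetic: neutral mass = m/z·|z| − shift, with [M+H]+, [M+Na]+,
  [M−H]− shipped.
* Confidence sublevels over isomer counts default to 1 → 3a, 2–20 → 3b,
  >20 → 3c; the binning is per-study configuration.

## Chemometrics

KMD-PCA standardizes columns to unit variance before eigendecomposition
(common chemometrics practice; configurable), drops zero-variance columns,
and fixes component signs by making each component's largest loading
positive. Confidence ellipses use the sample mean and covariance with
squared Mahalanobis radius χ²(level, 2 df); overlap is decided by
containment checks plus 720-point boundary sampling with a 1e-9 tolerance
on the Mahalanobis comparison — ample for ellipses whose axes differ by
orders of magnitude less than their separation, and exact cases (tangency)
are resolved to within sampling resolution. Ellipses are drawn on PCA
scores for KMD plots and on raw (RDBE, O/C) coordinates otherwise.

## Synthetic features

`generate_synthetic_features` emulates a positive-mode HRMS feature table
drawn from a library: true features are library masses as [M+H]+ ions with
Gaussian ppm mass error (default 1 ppm, a typical well-calibrated TOF
figure) and log-normal intensities; decoys are offset by ≥0.05 Da, more
than ten times any ppm-scale tolerance at lignin masses, so they must never
match. What this does *not* emulate: retention/mobility structure, isotope
patterns, adduct mixtures, in-source fragments, chemical noise, or
intensity-dependent mass error. Passing recall/decoy tests therefore
validate the matching arithmetic and tolerance handling, not performance on
real instrument data.

## Problem sizes and defaults

The test suite grows the conventional H/G/S library to degree 3–4 (691 and
~10⁴ unique oligomers) where exhaustive cross-checks (brute-force reversal
classes, per-record SMILES round-trips) are affordable, and uses the
state-space reduction for degree-6 claims. The demo registry holds ten
residues — the three canonical monolignols, their aldehyde and acid
variants, and vanillin — chosen as the smallest set that exercises every
flag, ring pattern and side-chain class. The vanillin residue additionally
has `sidechain_intact=false`: the β-1 correction term (−C3H4) encodes the
displacement of a three-carbon side chain, which a one-carbon residue
cannot supply, so the registry rather than the rule table carries that
restriction.

## Known limitations

* No branching; linear constitutions only.
* Reduced/modified linkage variants only via user-supplied rules; the
  packaged seven are the conventional set.
* Isomer counts are constitutional; stereoisomers are not distinguished.
* The snippet dictionaries cover the demo registry; new residue classes
  need new rows (QC reports the gaps).
* RDBE-window classification inherits the library's composition: residues
  with higher intrinsic RDBE (cinnamic-acid-like, flavonoid) shift and
  overlap the windows.
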