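# Methods

## Mutation classification

A clone is compared to its germline V gene position by position; the two
sequences must already share germline coordinates (equal length, no
indels — a length mismatch is an error, never a trigger for alignment,
matching the dash-for-identity alignment convention these panels are
published in). Each differing nucleotide yields one record carrying:

* **region** — from an explicit, 1-based, inclusive codon-interval map
  (Kabat-derived FR1/CDR1/FR2/CDR2/FR3). Computing Kabat numbering is out
  of scope; boundaries are inputs. Codons not covered by any interval are
  `JUNCTION` and are excluded from R/S tallies by default, because the
  germline origin of junction positions cannot be assigned.
* **R/S** — replacement vs silent under the standard genetic code,
  judged by comparing the *full germline codon* with the *full clone
  codon*. Two substitutions in one codon therefore share one codon-level
  verdict; the stepwise order of multi-hit codons is unknowable from
  endpoint sequences, so no per-step attribution is attempted. A change
  creating or destroying a stop codon is R (the encoded residue differs).
* **Ti/Tv** — transition iff both bases are purines or both pyrimidines.

**Counting unit.** The default counts every base substitution as one
mutation (a doubly hit codon contributes two counted mutations sharing one
R/S verdict), since all instances of substitution within a codon are
considered. The alternative convention — one event per mutated codon — is
available via `count_unit="codon"` because published tables do not always
state which convention they use.

An `indeterminate` mask (`mask_nt_positions`) excludes positions whose
substitution cannot be established from the available sequence sources
(e.g. a PDB-vs-patent discrepancy at one position) from all tallies.

## Stratified statistics

Each antibody is one stratum: a 2×2 table with rows CDR/FR and columns
R/S (`a` = CDR-R, `b` = CDR-S, `c` = FR-R, `d` = FR-S). Stratification
avoids the Simpson's-paradox distortions of pooling clones with different
mutation loads.

* **Mantel–Haenszel common OR**: Σaᵢdᵢ/nᵢ ÷ Σbᵢcᵢ/nᵢ. Zero cells vanish
  from the sums naturally; no pseudocounts are added. Per-stratum ORs are
  reported raw (+∞ on a zero denominator) with Haldane (+0.5 per cell) as
  an explicit option.
* **CMH test** (df = 1): (Σaᵢ − Σr₁ᵢc₁ᵢ/nᵢ)² ÷ Σ r₁ᵢr₂ᵢc₁ᵢc₂ᵢ/(nᵢ²(nᵢ−1)),
  upper-tail chi-square p. The continuity correction is **off** by
  default — recomputing the published panel without correction reproduces
  the printed statistic; the corrected variant is a flag. Strata with a
  zero margin carry no information and are skipped with a warning.
* **Breslow–Day test** (df = K−1): for each stratum, the expected
  `ãᵢ` consistent with the common OR and the stratum margins is the
  admissible root of the quadratic
  `(1−ψ)ã² + [n−r₁−c₁+ψ(r₁+c₁)]ã − ψr₁c₁ = 0`, and the statistic sums
  `(aᵢ−ãᵢ)²/Vᵢ` with `Vᵢ = (1/ãᵢ + 1/b̃ᵢ + 1/c̃ᵢ + 1/d̃ᵢ)⁻¹`. The MH
  estimator is the homogeneity null; Tarone's adjustment (subtracting
  `(Σaᵢ−Σãᵢ)²/ΣVᵢ`) is available behind a flag but off by default.
  Both tests are cross-validated in the test suite against statsmodels'
  independent implementation on 200 random tables to 1e-6.

P-values are printed to three decimals. The null calibration of the CMH
test is checked by simulation (10,000 independence replicates, four strata
of 60 draws each; the empirical type-I error at α = 0.05 must fall in
[0.035, 0.065]).

**Inherent R/S.** For every selected codon all nine single-base neighbours
are enumerated and classified by translation; the ratio of replacement to
silent outcomes is the selection-free expectation for that sequence
(+∞, flagged, when no silent neighbour exists — e.g. the single codon TGG).
Uniform-codon random ORFs give ≈3.1, consistent with the 2.9 figure
conventionally used as the somatic-hypermutation reference.

## Synthetic data

The generator defines the conditions under which the pipeline is tested:

* **Germline**: codons drawn uniformly from the 61 sense codons (no
  internal stops by construction); default length 98 codons (through the
  end of FR3) with Kabat-style VH intervals FR1 1–30, CDR1 31–35,
  FR2 36–49, CDR2 50–66, FR3 67–98.
* **Clones**: each codon site mutates independently with probability
  rate/3, where the per-region rate (expected substitutions per codon)
  defaults to FR1 0.015, CDR1 0.005, FR2 0.005, CDR2 0.10, FR3 0.03 —
  mutations concentrated in CDR2 with the flanking frameworks next, the
  pattern observed in the LeY VH panel, at a load of a few substitutions
  per ~300 nt V gene (a low-mutation, T-independent-like regime).
* **Ti/Tv**: the proposal ratio defaults to 0.5, i.e. all three
  alternative bases equally likely, under which transversions predominate
  2:1 as observed in the panel.
* **Multi-hit codons** are allowed by default; mutations that create a
  stop codon are allowed and labelled R (configurable to `forbid`, which
  redraws the codon's hits).
* Every mutation is recorded with its true position, bases, Ti/Tv class,
  codon-level R/S verdict and region, and the clone differs from germline
  at exactly the recorded positions — label-recovery tests are exact, not
  statistical.

What the generator does **not** emulate: AID hotspot motifs (WRC/GYW),
selection, clonal genealogies, insertions/deletions, and sequencing error.
Passing tests therefore demonstrate correctness of classification and
counting on substitution-only, indel-free data — they do not validate
germline inference or alignment, which are out of scope (sequences are
taken as pre-aligned, annotated inputs).

Toy structures are uniform random atom clouds (elements C/N/O, small
Gaussian partial charges) with optional constraints: an exact pinned
distance between named atoms, or a minimum separation between the two
groups (used to emulate a docked, non-interpenetrating interface).
Trajectories add isotropic Gaussian jitter of scale σ per coordinate to a
base structure, for which the per-atom RMSF about the mean has the closed
form √3·σ·√((F−1)/F).

## Structure metrics

* **Contacts**: inter-selection heavy-atom pairs at distance ≤ cutoff
  (4.0 Å default, boundary inclusive); hydrogens excluded unless asked.
* **Hydrogen bonds**: donor/acceptor typing comes from a residue/atom-name
  dictionary covering protein backbones and side chains plus the sugar
  residues of Lewis-type glycans (hydroxyl oxygens are both donor and
  acceptor, ring O5 acceptor only, GlcNAc N2 donor). Criteria — D···A
  ≤ 3.5 Å and D–H···A ≥ 120° — are configurable because the tools these
  panels were originally analyzed with do not publish theirs. Without
  explicit hydrogens the check is distance-only and each record says so.
  Atoms not in the dictionary are neither donor nor acceptor.
* **Energies**: hard-truncated pairwise sums in vacuo (no
  switching/shifting at the cutoff, no Ewald, no solvent model);
  Lorentz–Berthelot-style combination ε_ij = √(ε_iε_j),
  rmin_ij = rmin/2_i + rmin/2_j. Parameters resolve per atom from
  explicit overlays first, then from an element-keyed TSV bundled with
  the package (generic protein-force-field magnitudes; editable). The
  bundled table deliberately carries **no default charges**: an atom
  without an assigned charge is an error listing the offending atoms,
  never a silent zero. Pairs closer than 0.1 Å are rejected as geometry
  errors. Absolute energy magnitudes depend entirely on the
  parameterisation, so published per-complex energy tables computed with
  a commercial force field on modeled structures are not reproduction
  targets; rankings and signs on a *shared* parameterisation are
  meaningful, and the per-residue partition sums to the whole-selection
  decomposition to 1e-6 kcal/mol by construction.
* **RMSD/RMSF**: Kabsch (SVD) superposition with the determinant sign
  fix; RMSF superposes every frame onto the running average structure
  (backbone fit by default) and iterates the average to convergence
  (tolerance 1e-8, max 10 rounds). A single-frame trajectory yields zeros
  with a warning.
* **Ramachandran coding**: φ/ψ by the standard IUPAC sign convention in
  (−180°, 180°]; termini and residues with incomplete backbones are
  flagged and skipped. The default letter partition is: φ ≤ 0 →
  'a' if −120° < ψ ≤ 50° else 'b'; φ > 0 → 'l' unless |ψ| > 120° ('e').
  These boundaries approximate the published quadrant codings and are
  configurable; the CDR-H3 take-off report is therefore the code string
  itself plus a heuristic kinked-plus-bulge (K⁺) flag when 'bab' appears,
  not a definitive canonical-class assignment.

Two dihedral facts worth recording: reversing the atom order of a
quadruple *preserves* the dihedral (χ(D,C,B,A) = χ(A,B,C,D)); mirror
reflection negates it. The tests assert both.

## Numerical and design choices

* PDB reading goes through gemmi; alternate conformations keep the
  highest-occupancy altloc. Writing uses a canonical fixed-width
  formatter, so write(read(x)) is byte-stable for files the package
  produced; PDB coordinates carry three decimals, which bounds the
  precision of any file-mediated round trip.
* MH/CMH/Breslow–Day are implemented directly from their defining
  formulas (they are the analytical core of the package); library
  implementations serve only as independent cross-checks in tests.
* The published VH panel counts ship as a per-region TSV and flow through
  the same tabulation path (`Total-FR`/`Total-CDR` derivation →
  `StratifiedTable`) as freshly classified data.
* The corresponding VL analysis cannot be reproduced: the underlying
  per-antibody VL table was not published.
* Test problem sizes (100-seed recovery sweeps, 10,000-replicate null
  calibration, 500-frame RMSF checks, 40+40-atom interface fixtures) were
  chosen to make Monte-Carlo bounds tight while keeping the default suite
  in the low seconds.
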