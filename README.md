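# abmut

Somatic-mutation selection analysis of antibody V genes, with stratified
contingency statistics and structural interface metrics for
antibody–carbohydrate complexes.

## The problem

Antibodies raised against carbohydrate antigens such as the tumor-associated
Lewis Y (LeY) tetrasaccharide typically arise from T-cell-independent
responses, yet their V genes carry a small number of somatic mutations. Two
questions follow from a panel of clonally related antibodies and their
germline V-gene precursor:

1. **Are replacement mutations enriched in the antigen-binding loops?**
   Every nucleotide difference from germline is classified by region
   (framework FR1–FR3 vs complementarity-determining CDR1–CDR2, Kabat
   intervals; positions beyond FR3 form the V(D)J junction and are
   excluded), by effect (replacement R vs silent S, judged codon-wise
   against the standard genetic code) and by substitution class
   (transition vs transversion). Because each antibody contributes few
   mutations, the clones are analyzed as strata of 2×2 tables
   (CDR/FR × R/S) rather than pooled — pooling invites Simpson's paradox.
   `abmut` computes the Mantel–Haenszel common odds ratio

   `OR_MH = Σᵢ(aᵢdᵢ/nᵢ) / Σᵢ(bᵢcᵢ/nᵢ)`,

   the Cochran–Mantel–Haenszel chi-square test of association (df = 1) and
   the Breslow–Day test of odds-ratio homogeneity (df = K−1), plus the
   *inherent* R/S ratio of any region — the R/S a random mutator would
   produce, found by enumerating all nine single-base neighbours of every
   codon (≈2.9–3.1 for random coding sequence).

2. **What does the interface look like, and how rigid is it?** For
   PDB-format complexes and multi-MODEL trajectories, `abmut` measures Van
   der Waals contacts (heavy-atom pairs ≤ 4 Å), intermolecular hydrogen
   bonds (donor–acceptor ≤ 3.5 Å, D–H···A ≥ 120° when hydrogens are
   present), a vacuum nonbonded interaction-energy decomposition
   (Coulomb with constant 332.0637 kcal·Å/(mol·e²) plus Lennard-Jones,
   14 Å spherical cutoff, dielectric 1) partitionable per residue,
   Kabsch-superposed RMSD, RMSF about the iteratively superposed
   trajectory-average structure, and φ/ψ Ramachandran letter codes used to
   describe the CDR-H3 take-off conformation (a `bab` code marks a
   kinked-plus-bulge, K⁺, candidate).

A fully labelled synthetic-data module generates germline/clone pairs with
planted mutations (region-specific rates, Ti/Tv bias) and toy
complexes/trajectories with known geometry, so the entire pipeline is
testable without any external download.

## Worked example

The per-region replacement/silent counts of the four LeY-reactive VH
domains (BR55-2, B3, BR96, mu3S193 against the VH7183.a13.20 germline) ship
with the package. Running the stratified analysis:

```python
from importlib import resources
from abmut.mutations import read_mutation_table
from abmut.stats import StratifiedTable, analyze

path = resources.files("abmut.data") / "ley_vh_mutation_table.tsv"
table = StratifiedTable.from_mutation_table(read_mutation_table(path))
report = analyze(table)
print(f"MH common OR = {report['mh_common_or']:.2f}")
print(f"CMH chi-square = {report['cmh']['statistic']:.2f}, "
      f"p = {report['cmh']['p_value']:.3f}")
print(f"Breslow-Day = {report['breslow_day']['statistic']:.2f}, "
      f"p = {report['breslow_day']['p_value']:.3f}")
```

prints

```
MH common OR = 6.26
CMH chi-square = 3.92, p = 0.048
Breslow-Day = 1.08, p = 0.781
```

i.e. the odds of a mutation being replacement rather than silent are about
six-fold higher in the CDRs than in the frameworks, the association is
significant at the 5% level, and the per-antibody odds ratios are mutually
consistent with that single common value. The same numbers come from the
command line:

```bash
abmut simulate --seed 5 --n-clones 6 --outdir sim/      # synthetic panel
abmut classify sim/germline.fasta sim/clones.fasta sim/regions.yaml --outdir cls/
abmut stats cls/mutation_table.tsv --outdir st/
abmut structure energy complex.pdb --sel-a H --sel-b L --charges charges.tsv
```

## Layout

| module | contents |
| --- | --- |
| `abmut.regions` | FR/CDR codon-interval maps, annotated sequences, YAML/TSV I/O |
| `abmut.synthetic` | germline/clone simulator with labelled ground truth; toy structures |
| `abmut.mutations` | R/S, Ti/Tv and region classification; mutation tables; inherent R/S |
| `abmut.stats` | per-stratum ORs, MH common OR, CMH test, Breslow–Day test |
| `abmut.structure` | PDB I/O, contacts, H-bonds, energies, RMSD/RMSF, Ramachandran codes |
| `abmut.cli` | `abmut simulate / classify / stats / structure …` |

See `docs/methods.md` for the statistical model, conventions and known
limitations.
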