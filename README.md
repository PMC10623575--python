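# lrip

Ligand–residue interaction profiling and function-based agonist screening.

`lrip` computes per-residue ligand interaction energies from receptor–ligand
conformational ensembles (multi-model PDB snapshots plus a per-atom force-field
parameter table), averages them into interaction profiles, compares those
profiles to agonist/antagonist reference signatures, and classifies compounds
with a thresholded correlation / binding-energy decision rule
(R > 0.84 and ΔE < −10 kcal/mol by default).

Energy model, per snapshot:

- **Coulomb** and **12-6 Lennard-Jones** intermolecular sums (exact O(N²),
  no cutoffs),
- **polar solvation** via generalized Born with Hawkins–Cramer–Truhlar
  pairwise-descreening effective radii and the Still interpolation formula,
  decomposable into per-pair cross terms,
- **nonpolar solvation** as γ·SASA + β with a deterministic Shrake–Rupley
  sphere lattice,
- a single-trajectory binding-energy report (complex − receptor − ligand on
  identical coordinates) with a pluggable weighted-SASA entropy estimator.

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent oracles (numerical quadrature for the
descreening integral, brute-force pair loops, closed forms) and
hypothesis-based property tests; `tests/test_acceptance.py` holds the
acceptance criteria.

## CLI

```sh
# generate a seeded toy complex (PDB + parameter + label tables)
lrip simulate complex --seed 1 --n-snapshots 5 --out toy/

# validate inputs
lrip read-check toy/complex.pdb toy/params.tsv toy/labels.tsv

# per-snapshot ligand-residue decomposition
lrip decompose toy/complex.pdb toy/params.tsv toy/labels.tsv --out rows.tsv

# average into a profile, build a signature, compare
lrip profile rows.tsv --id cmpd6 --state CB2_active --out cmpd6.profile.tsv
lrip signature ref1.tsv ref2.tsv --rule union --out cb2_active.sig.tsv
lrip compare cmpd6.profile.tsv cb2_active.sig.tsv

# binding-energy report
lrip energy toy/complex.pdb toy/params.tsv toy/labels.tsv \
    --stride-de 1 --stride-tds 25 --out report.tsv

# classification and evaluation against assay outcomes
lrip classify evidence.tsv --r-threshold 0.84 --de-threshold -10 --out calls.tsv
lrip evaluate calls.tsv outcomes.tsv

# packaged fixture tables
lrip fixture evaluation_42 --out eval42.tsv
```

Evidence TSV columns: `compound_id, docking_pass, md_stable, r_active, de`
(optional `r_inactive`, `receptor`). Outcomes TSV: `compound_id, truth`
with truth one of `AGONIST | ANTAGONIST | INACTIVE`.

## Layout

- `src/lrip/complex_io.py` — ensemble / parameter / label / profile I/O
- `src/lrip/energetics.py` — pair energies, Born radii, GB, SASA, decomposition
- `src/lrip/profiles.py` — profiles, signatures, similarity metrics
- `src/lrip/binding.py` — binding-energy aggregation and the energy gate
- `src/lrip/classify.py` — decision flow and prediction evaluation
- `src/lrip/synthetic.py` — seeded toy complexes, correlated profile
  simulation, packaged fixture tables
- `src/lrip/cli.py` — the `lrip` command
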