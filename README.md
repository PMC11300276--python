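# nblib

A design toolkit for synthetic humanized nanobody (VHH) phage-display
libraries, together with the quantitative assay analyses used to characterize
selected binders.

The pipeline it implements:

1. **`seq_core`** — sequence primitives: amino-acid / degenerate-nucleotide
   types, an IMGT-style region scheme for VHH domains (FR1 1–26, CDR1 27–38,
   FR2 39–55, CDR2 56–66, FR3 67–104, CDR3 105–117, FR4 118–128; position 66
   counted inside CDR2), anchored region annotation, global alignment,
   translation/back-translation, FASTA/TSV I/O.
2. **`repertoire_analysis`** — CD-HIT-style greedy identity clustering,
   complex-dataset curation (CDR3 length → resolution → identity → distinct
   antigen), per-position frequency profiles, consensus distillation, and the
   FR2-hallmark vs CDR3-length association.
3. **`scaffold_design`** — humanization of a template toward a germline:
   hallmark substitutions at IMGT 42/49/50/52 (L50 substitutions carry a
   caution flag), consensus-framework substitutions ranked by conservation,
   framework-identity humanness scoring, scaffold emission.
4. **`diversity_design`** — per-position randomization plans (fixed /
   anchored / natural-mimic, Cys mass removed) for CDR1/CDR2 (fixed length 8)
   and CDR3 length classes {8, 11, 14}; exhaustive degenerate-codon
   optimization over all 3,375 IUPAC triplets minimizing total-variation
   distance plus stop/Cys penalties.
5. **`library_build`** — overlap-extension primer/fragment planning with
   SfiI/NotI flanks, in-silico assembly, seeded library sampling,
   synthesis-error simulation, clone-defect classification
   (no_insert > large_region_missing > base_shifting > base_missing >
   stop_codon > correct), QC statistics (insertion/correctness/redundancy)
   and serial-dilution titer.
6. **`assay_analysis`** — mean-residue molar ellipticity, two-state melt fits
   with linear baselines (Tm, fraction folded), thermal reversibility,
   four-parameter-logistic binding fits with seeded bootstrap CIs
   (EC50 reported as apparent KD), positivity ratios (strictly > 2), and
   wound-healing rates.
7. **`synthetic_data`** — seeded generators for every input above:
   repertoires with controlled positional conservation and planted
   hallmark/length associations, melt curves, binding series, and
   error-bearing clone reads with ground-truth defect labels.

## CLI

The `nblib` entry point exposes one subcommand per stage. A full in-silico
round trip using the packaged example scaffold:

```bash
nblib gen repertoire -n 200 --seed 2 --out rep.fasta
# region lengths of the packaged scaffold: FR1,CDR1,FR2,CDR2,FR3,CDR3,FR4
python -c "from nblib.synthetic_data import example_scaffold as s; \
  from nblib.seq_core import write_fasta; write_fasta([s().sequence], 'scaffold.fasta')"
nblib profile rep.fasta --anchor scaffold.fasta --anchor-regions 25,8,17,8,38,14,11 --out profile.tsv
nblib design-diversity --profile profile.tsv --out spec.yaml
nblib codons --spec spec.yaml --out plan.tsv
nblib primers --scaffold scaffold.fasta --scaffold-regions 25,8,17,8,38,14,11 \
  --spec spec.yaml --plan plan.tsv --out-prefix primers
nblib sample-library --scaffold scaffold.fasta --scaffold-regions 25,8,17,8,38,14,11 \
  --spec spec.yaml --plan plan.tsv -n 10000 --seed 7 --out clones.fasta
nblib qc --picked 50 --negative 2 --sequenced 30 --incorrect 9
```

Assay analyses read simple CSVs:

```bash
nblib gen melt --tm 73.7 --noise-sd 50 --seed 0 --out melt.csv
nblib fit-melt melt.csv
nblib gen elisa --ec50-nm 22.16 --noise-sd 0.05 --seed 42 --out elisa.csv
nblib fit-elisa elisa.csv --seed 42
nblib reversibility --pre -9000 --post -8703
nblib ratio --experimental 1.0 --control 0.4
```

Other subcommands: `annotate`, `dedup`, `hallmark-assoc`, `curate`,
`design-scaffold`, `simulate-errors`, `titer`, `wound-rate`,
`gen clones`. Run `nblib <command> --help` for options.

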