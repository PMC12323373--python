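# pulrecon

Genome-mining toolkit for marine Bacteroidota: consensus CAZyme and
SusC/SusD marker annotation, rule-based polysaccharide-utilization-locus
(PUL) prediction with substrate classification (including alginate
utilization loci, AULs), genome-level degradative-capacity statistics
(G+C, per-Mb role densities, P/C ratio, fragment-based reciprocal-best-hit
ANI, 16S identity), and event-cost parsimony (duplication–transfer–loss)
reconciliation of gene trees against a species tree.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` implements the acceptance criteria; the
accession spot checks (criterion 6) need four GenBank records under
`data/accessions/` (see below) and fail with an explanation when absent.

## Command line

```sh
pulrecon io validate genes.gff3
pulrecon annotate --cazy cazy.tsv --pfam pfam.tsv --tigrfam tigrfam.tsv \
    --merops merops.tsv --sulfatlas sulfatlas.tsv --out roles.tsv
pulrecon predict-puls --genes genes.gff3 --roles roles.tsv --out puls.tsv
pulrecon stats --fasta genome.fasta --roles roles.tsv
pulrecon ani a.fasta b.fasta
pulrecon ident16s a16s.fa b16s.fa
pulrecon reconcile --gene g.nwk --species s.nwk --map m.tsv \
    --loss 1 --dup 2 --hgt 3
pulrecon simulate genome --seed 1 --decoys --out sim/
pulrecon simulate family --species s.nwk --seed 1 --out fam/
pulrecon run --config cohort.yaml
```

Key defaults (all configurable): CAZyme families require agreement of 2 of
the 3 dbCAN-style tools (HMMER/DIAMOND/eCAMI) at the subfamily-stripped
family level; SusC = TIGR04056/TIGR04057, SusD = PF07980/PF12741/PF12771;
peptidase/sulfatase/marker hits require e-value < 1e-15 (strict); PUL rules
use a 10-gene window, ≥5 GH genes for the lone-SusC rule, and a SusC/D pair
rank gap ≤ 2; reconciliation costs are loss = 1.0, duplication = 2.0,
transfer = 3.0.

## Layout

- `src/pulrecon/io_formats.py` — GFF3/GenBank/TSV gene tables, hit tables,
  FASTA, leaf-map TSV; domain types.
- `src/pulrecon/annotation.py` — consensus CAZyme voting, SusC/SusD and
  peptidase/sulfatase calling, role merging.
- `src/pulrecon/pul_detection.py` — SusC/D pairing, the two PUL seed rules,
  locus merging, substrate/AUL classification, cohort summaries.
- `src/pulrecon/genome_stats.py` — G+C, lengths, densities, P/C ratio,
  reciprocal-best-hit fragment ANI (1020-bp fragments), 16S identity.
- `src/pulrecon/reconciliation.py` — undated DTL parsimony DP, unrooted
  gene-tree root search, family-history classification.
- `src/pulrecon/synthetic_data.py` — planted-PUL genome simulator (with
  enumerated decoys), genome mutator, gene-family evolution with recorded
  true events.
- `src/pulrecon/cli.py` — `pulrecon` entry point.
- `tests/dtl_oracle.py` — independent brute-force reconciliation oracle,
  exhaustive topology enumeration, closed-form duplication–loss cost.
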