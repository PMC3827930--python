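# lipmine

Genome-mining pipeline for discovering versatile sterol esterase/lipase
candidates in protein FASTA proteomes.  The pipeline reproduces, as
reusable and tested components, a classic mining strategy for the
*Candida rugosa* lipase-like family (abH03.01):

1. **Screen** (`lipmine.screen`) — keyword harvest of annotated
   lipases/esterases, exact-sequence de-duplication, and filtering for the
   family's conserved motifs (GESAG catalytic shoulder + GGGF oxyanion
   hole).
2. **Place** (`lipmine.phylo`) — Needleman-Wunsch distances (BLOSUM62,
   affine gaps) + neighbor joining to place candidates among
   family-labelled references, then selection of the candidates closest to
   a designated "versatile" reference subset.
3. **Features** (`lipmine.features`) — transfer of Lip3-anchored
   annotations (catalytic Ser/Glu/His triad, oxyanion motif, the
   lid-delimiting Cys pair) onto each candidate by global alignment;
   lid hydrophobic-residue count; N-glycosylation sequon scan
   (N-X≠P-[S/T]); signal-peptide stripping with externally supplied
   cleavage sites.
4. **Tunnels** (`lipmine.tunnels`) — a simplified grid/BFS tunnel finder
   from the catalytic serine (voxelization in a canonical frame, free-space
   breadth-first search, convex-hull surface truncation, line-of-sight
   smoothing), with lining residues at a 4 Å cutoff, hydrophobic lining
   percentage, and straight/bent shape classification.
5. **Report** (`lipmine.report`) — per-candidate substrate-preference
   table: affinity class from lid hydrophobicity thresholds and an
   efficiency flag from tunnel shape, with a deterministic run manifest.

`lipmine.synthetic` generates proteomes with planted motif-bearing
candidates and CA-only toy structures with tunnels of known lining and
straightness, so every stage is testable offline against constructed
ground truth.

## CLI

```bash
# screening
lipmine screen --fasta proteome.fasta --motif GESAG --motif GGGF \
    --keywords esterase,lipase --out screen.tsv

# family placement (panel FASTA headers carry family= and versatile= tokens)
lipmine place --candidates survivors.fasta --panel panel.fasta --top-k 6

# sequence features against a reference annotation
lipmine features --candidates survivors.fasta --reference lip3.fasta \
    --ref-annot lip3_annot.yaml --cleavage cleavage.tsv

# tunnels from the catalytic serine
lipmine tunnels --pdb model.pdb --seed-residue 209 --cutoff 4.0

# full pipeline
lipmine -v run --config pipeline.yaml

# synthetic test data
lipmine synth proteome --n-planted 3 --out-fasta p.fasta --out-truth t.tsv
lipmine synth structure --bend-angle 90 --out-pdb toy.pdb --out-truth t.tsv
```

A pipeline config looks like:

```yaml
outdir: out
proteomes: [proteome.fasta]
panel: panel.fasta
top_k: 6
reference: lip3.fasta          # first record used
ref_annot: lip3_annot.yaml     # optional; default: packaged Lip3 annotation
cleavage: cleavage.tsv         # optional id -> cleavage_pos table
structures:
  - {candidate: cand_01, pdb: model.pdb, seed_residue: 209}
affinity_thresholds: {high_min: 13, low_max: 10}
```

## Conventions

- All sequence coordinates are 1-based on the mature chain (after optional
  signal stripping); spans are inclusive.
- The lid is the residue stretch strictly between the two conserved
  lid-delimiting Cys residues.
- The default hydrophobic set is {A, V, L, I, M, F, W, P}; it is a config
  value everywhere it is used.
- Tunnel lining = residues with any atom within the cutoff (default 4 Å)
  of any centerline point; percentages are rounded half-up to integers.
- Tunnels are classified straight when straightness (chord / arc length)
  ≥ 0.85.
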