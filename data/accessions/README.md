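# Reference accession sequences (not bundled)

The accession-based acceptance checks compare pipeline outputs against
published statistics of real reference proteins.  The sequences are not
redistributed with this repository and the build environment has no
network access, so the corresponding tests fail until you provide them.

To enable those checks, download the canonical FASTA for each accession
from UniProt (https://rest.uniprot.org/uniprotkb/<ACC>.fasta) and save it
here as `<ACC>.fasta`:

| file           | protein                                  |
|----------------|------------------------------------------|
| `P20261.fasta` | *Candida rugosa* lipase 1 (Lip1)         |
| `P32946.fasta` | *C. rugosa* lipase 2 (Lip2)              |
| `P32947.fasta` | *C. rugosa* lipase 3 (Lip3)              |
| `P32948.fasta` | *C. rugosa* lipase 4 (Lip4)              |
| `P32949.fasta` | *C. rugosa* lipase 5 (Lip5)              |
| `Q2TFW1.fasta` | *Ophiostoma piceae* sterol esterase (OPE)|

Signal-peptide cleavage positions: Lip1-Lip5 default to 15 (549-residue
precursors, 534-residue mature chains).  For other entries (e.g. OPE),
add a tab-separated `cleavage.tsv` in this directory:

```
id	cleavage_pos
Q2TFW1	18
```

using the signal-peptide end annotated in UniProt.  Then re-run

```
pytest tests/test_acceptance.py -k Accession
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
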