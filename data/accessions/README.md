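# data/accessions

Drop plain-FASTA copies of the four deposited GenBank records here to
enable the accession-based acceptance targets (t1–t6) and the criterion-6
tests:

- `CP169638.1.fasta` — strain C4 chromosome assembly
- `CP169639.1.fasta` — strain GZD32 chromosome assembly
- `PP762181.fasta` — strain C4 16S rRNA gene
- `PP762183.fasta` — strain GZD32 16S rRNA gene

They are not bundled because the build sandbox has no network route to
NCBI. Example fetch (requires network):

```sh
for acc in CP169638.1 CP169639.1 PP762181 PP762183; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" \
    > "data/accessions/${acc}.fasta"
done
```
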