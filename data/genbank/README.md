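# GenBank downloads (not shipped)

Four tests compare against deposited records and look for uncompressed
FASTA files in this directory:

| file | contents |
|---|---|
| `popset_40556720.fasta` | the deposited 16S rRNA clone libraries (PopSet 40556720; accessions OQ518241-OQ518253, OQ518371, OQ519263-OQ519273, OQ726108-OQ726109, OQ913398-OQ913416) |
| `clade_alignment.fasta` | the clone sequences aligned together with the *Chlorobaculum* type-strain 16S references |
| `CP104202.1.fasta` | genome of the hot-spring isolate MV4-Y |
| `NC_002932.3.fasta` | genome of *Cba. tepidum* TLS |
| `NZ_CP017305.fasta` | genome of *Cba. limnaeum* DSM 1677 |

Fetch with NCBI efetch, e.g.:

```bash
curl -o CP104202.1.fasta \
  'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nucleotide&id=CP104202.1&rettype=fasta&retmode=text'
```

Without these files the corresponding tests fail with a message pointing
here; all other tests are self-contained.
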