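# Accession FASTAs (not bundled)

The regression checks in `mitoscreen.regression` expect one FASTA per
public sequence record in this directory, named `<accession>.fasta`:

LC595639, LC592696, LC592697, LC592698, LC592699,
DQ167400, JF281153, D00293

These are large third-party database records and are therefore not shipped
with the package.  With network access, fetch them once:

```python
from mitoscreen.regression import fetch_accessions
fetch_accessions("data/accessions")
```

or run `python examples/accession_regression.py`.
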