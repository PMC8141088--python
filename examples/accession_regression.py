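"""Regression checks against the deposited genome accessions (needs network
once, to fetch the public records; afterwards runs offline).

Recomputes the headline numbers from the deposited sequences: subgenome
lengths, the two-candidate specificity screen, orf312/orf288 identities,
the 48-bp cox2-exon block, the shared 98-bp prefix at subgenome-1 position
114,769, the B1 plasmid identity and the ORF312 transmembrane helix.
"""

import json
from pathlib import Path

from mitoscreen.regression import fetch_accessions, run_accession_checks

data_dir = Path(__file__).resolve().parent.parent / "data" / "accessions"
try:
    results = run_accession_checks(data_dir)
except FileNotFoundError:
    print(f"fetching accession FASTAs into {data_dir} ...")
    fetch_accessions(data_dir)
    results = run_accession_checks(data_dir)

print(json.dumps(results, indent=2))
print("\nThese are the deposited-sequence equivalents of the quantities the "
      "synthetic test-suite checks against its truth manifest.")
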