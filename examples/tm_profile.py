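"""Sliding-window hydropathy profile and transmembrane helix prediction.

The chimeric candidate's peptide carries a planted hydrophobic block at
residues 29-55; the Kyte-Doolittle window predictor reports one helix
overlapping it — the membrane anchor typical of CMS-associated proteins.
"""

from Bio.Seq import Seq

from mitoscreen import SimConfig, hydropathy_profile, predict_tm, simulate

bundle = simulate(SimConfig(seed=5))
nt = bundle.manifest["chimera_nt"]
peptide = str(Seq(nt[:-3]).translate())

profile = hydropathy_profile(peptide, window=19)
peak = int(profile.argmax()) + 1
print(f"peptide: {len(peptide)} aa; hydropathy peak {profile.max():.2f} "
      f"at residue {peak}")

for helix in predict_tm(peptide, threshold=1.6, min_len=18):
    print(f"predicted TM helix: residues {helix.start_aa}-{helix.end_aa} "
          f"(mean hydropathy {helix.mean_hydropathy})")
lo, hi = bundle.manifest["chimera"]["tm_interval_aa"]
print(f"planted hydrophobic block: residues {lo}-{hi}")
print("\nA single N-terminal helix means the candidate protein can insert "
      "into the inner mitochondrial membrane.")
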