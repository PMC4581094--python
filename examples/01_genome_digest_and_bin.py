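"""In-silico restriction digestion and fragment binning.

Builds a random 50-kb chromosome, digests it at GATC (DpnII) sites and
groups fragments into 20-fragment bins, the resolution used for
genome-wide contact maps.
"""

import numpy as np

import telohic as th

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=50_000))

frag_map = th.digest_genome([("chrToy", seq)], site="GATC")
bins = th.bin_fragments(frag_map, F=20)

lengths = frag_map.fragments["chrToy"][:, 1] - frag_map.fragments["chrToy"][:, 0]
print(f"fragments: {frag_map.n_fragments()} (mean length {lengths.mean():.0f} bp)")
print(f"bins at 20 fragments/bin: {len(bins)}")
print(f"first bin: {bins.chrom[0]}:{bins.start[0]}-{bins.end[0]} "
      f"(fragments {bins.frag_lo[0]}..{bins.frag_hi[0]})")
# A random sequence has a GATC roughly every 4^4 = 256 bp, so ~195
# fragments and ~10 bins are expected for 50 kb.
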