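"""7mer-m8 seed matching and the targeted-DEG summary table.

The seed site is the reverse complement of mature nucleotides 2-8 (U -> T);
it is searched exactly along each 3'UTR. The summary reports, per
seed-identical miRNA group, how many DE genes carry at least one site.
"""

import pandas as pd

from micronet import extract_seed_site, scan_utrs, targeted_fraction
from micronet.io import SequenceRecord

mature = SequenceRecord("mir-x", "UAGCAGCACAUCAUGGUUUACA")
site = extract_seed_site(mature)
print(f"mature {mature.seq}")
print(f"seed nt 2-8 = {mature.seq[1:8]} -> DNA search site {site}")

utr = SequenceRecord("geneA", "AAATGCTGCTAATGCTGCTTT")
table = scan_utrs("mir-x", site, [utr])
print(f"sites in {utr.id}: n={table.loc[0, 'n_sites']} at offsets {table.loc[0, 'offsets']}")

# Summary arithmetic: per-miRNA targeted-DEG counts over a 432-gene DE set
degs = [f"deg{i:03d}" for i in range(432)]
sets = {"mir-15b": degs[:125], "mir-30a/mir-30e": degs[84:214], "mir-7142-3p": degs[:54]}
matches = pd.DataFrame(
    [{"mirna_id": m, "seed7": site, "gene_id": g, "n_sites": 1, "offsets": "0"}
     for m, genes in sets.items() for g in genes]
)
summary = targeted_fraction(matches, degs, {k: [k] for k in sets})
print(summary.to_string(index=False))
# pct_of_degs is the share of all DE genes with >= 1 site for that seed group
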