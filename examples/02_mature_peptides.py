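"""Excise mature peptides from a precursor's mature region.

The classic FMRFamide-type organisation: tandem peptide copies, each
followed by a glycine-extended dibasic cleavage site (GKR).  The glycine is
the amide donor, so every excised copy is reported C-terminally amidated;
an N-terminal glutamine would additionally be flagged as pyroglutamate.
"""

from prospect import excise_peptides, scan_cleavage_sites

mature = "FMRFGKRFMRFGKRQRPWGKR"
sites = scan_cleavage_sites(mature)
print(f"mature region : {mature}")
print(f"cleavage sites: {[(s.span, s.core) for s in sites]}")
print()
for p in excise_peptides(mature, sites):
    mods = []
    if p.amidated:
        mods.append("amide (-NH2)")
    if p.pyroglutamate:
        mods.append("pyroGlu")
    print(f"  {p.sequence:<6} span={p.span}  {', '.join(mods) or 'unmodified'}")
print("\nEach peptide is one predicted bioactive product; the flags are the")
print("post-translational modifications implied by its flanking context.")
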