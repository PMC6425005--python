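"""Classify peptide families by their phyletic distribution.

A family's origin is the last common ancestor of the terminal taxa it was
detected in, on the default backbone (Conchifera/Aculifera inside
Mollusca, nested in Lophotrochozoa > Protostomia > Bilateria > Eumetazoa).
The complement matrix tabulates, per taxon, the minimum number of families
present (at least one detected member).
"""

from prospect import CladeTree, FamilyAssignment, complement_matrix

tree = CladeTree.default()
families = [
    FamilyAssignment("FMRFamide-like", ["a", "b", "c"],
                     {"Gastropoda", "Polyplacophora", "Annelida", "Chordata"}),
    FamilyAssignment("FCAP-like", ["d", "e"], {"Gastropoda", "Rotifera"}),
    FamilyAssignment("PXRX-like", ["f"], {"Gastropoda", "Bivalvia", "Scaphopoda"}),
]
for fam in families:
    fam.classify(tree)
    print(f"{fam.family_id:<15} taxa={sorted(fam.taxa_present)}")
    print(f"{'':<15} origin = {fam.origin}")

taxa = ["Gastropoda", "Bivalvia", "Scaphopoda", "Polyplacophora", "Annelida", "Rotifera"]
matrix, counts = complement_matrix(families, taxa)
print("\nminimum complement per taxon:")
print(counts.to_string())
print("\nAn origin deeper than Mollusca means the family predates the phylum;")
print("counts are minima because absence of evidence is not evidence of loss.")
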