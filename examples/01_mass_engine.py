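"""In-silico Glu-C digestion and light/heavy acyl peptide masses.

Digests a short protein, picks a lysine-containing peptide, and prints the
doubly charged precursor m/z of its endogenous (light) acetyl form and its
chemically labeled (heavy, acetyl-d3) form. The pair differs by 3 mass units
per labeled site, i.e. 1.51 m/z at charge 2 - the spacing the SWATH workflow
relies on to separate the two channels.
"""

from acylswath import AcylPeptide, digest_gluc, peptide_mono_mass, precursor_mz

protein = "MEGFKRIAEDLQKDGRISNVE"
print(f"Glu-C digest of {protein} (0 missed cleavages):")
for pep, start, end in digest_gluc(protein, 0):
    print(f"  {pep:12s} residues {start}-{end}")

seq = "GFKRIAE"  # one internal lysine at position 3
for state in ("light", "heavy"):
    pep = AcylPeptide(seq, charge=2, acyl_sites=((3, "acetyl", state),))
    mz = precursor_mz(peptide_mono_mass(pep), 2)
    print(f"{seq} K3 {state:5s} acetyl, 2+ precursor m/z = {mz:.2f}")
print("The heavy-minus-light difference is 3.0188/2 = 1.5094 m/z: both forms")
print("must fall inside one SWATH isolation window to be quantified together.")
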