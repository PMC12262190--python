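"""Build the mucin model peptide as an ideal polyproline-II helix.

The model peptide is two tandem KEPAPTTP-like repeats of the lubricin
mucin domain (residues 393-410, sequence PKEPAPTTTKEPAPTTPK).  Every
threonine except Thr401 carries an O-linked glycan flag.  We build the
backbone with every residue at the canonical PPII dihedrals
(phi, psi) = (-75, 145) degrees, verify that measuring the structure
returns those angles, and fit the helix parameters.
"""

import mucinppii as m

model = m.PeptideModel.mucin_model_peptide()
print("sequence:         ", model.sequence)
print("residue numbers:  ", model.residue_numbers[0], "-",
      model.residue_numbers[-1])
print("glyco sites:      ", sorted(model.glyco_sites))
print("high-PPII residues per KEPAPTTP repeat:",
      m.count_high_ppii_residues("KEPAPTTP"))

backbone = m.build_backbone(model)          # (R, 4, 3): N, CA, C, O
phi, psi = m.measure_dihedrals(backbone)
print(f"\nmeasured interior dihedrals: phi={phi[9]:.6f}, psi={psi[9]:.6f}")

twist, rise, residues_per_turn = m.helix_parameters(backbone)
hand = "left" if twist < 0 else "right"
print(f"helix fit: twist={twist:.2f} deg/residue ({hand}-handed), "
      f"rise={rise:.2f} A, {residues_per_turn:.3f} residues/turn")

m.write_pdb("ppii_model_peptide.pdb", backbone, model)
print("\nwrote ppii_model_peptide.pdb")
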