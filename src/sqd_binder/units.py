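"""Unit conventions: energies in Hartree, lengths in Angstrom."""

HARTREE_TO_KCAL_PER_MOL: float = 627.509474
"""Conversion constant from Hartree to kcal/mol, defined once package-wide."""
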