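"""Residue-name based classification of atoms into moiety classes.

Every atom in a system belongs to exactly one moiety class:

``amino-acid``
    Polypeptide residues (the LU domain, termini and linker).
``glycan``
    Carbohydrate residues of N-/O-glycans (GlcNAc, Man, Gal, Fuc, Neu5Ac, ...).
``gpi``
    Residues of the glycosylphosphatidylinositol anchor: the membrane-embedded
    phosphatidylinositols (DSPI, SAPI), glucosamine (GlcN) and
    phosphoethanolamine (PEtN).  Mannoses shared between the GPI core and
    glycans default to ``glycan``; override per system if needed.
``lipid``
    Bilayer lipids (CHARMM names) and cholesterol.
``solvent`` / ``ion``
    Water models and monatomic ions.

Classification is a plain residue-name lookup so that it works on any PDB/GRO
file without connectivity; user rules are merged over the defaults.
"""

from __future__ import annotations

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # CHARMM protonation-state variants
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
]

LIPIDS = [
    "POPC", "DPPC", "DOPC", "DSPC", "DMPC", "DLPC",
    "POPE", "DOPE", "DPPE", "POPS", "DOPS", "POPG", "DOPG", "POPI",
    "PSM", "SSM", "NSM", "LSM", "DPSM", "CER160",
    "CHL1", "CHOL", "ERG",
]

GLYCANS = [
    # common PDB/CHARMM carbohydrate residue names
    "NAG", "BGLCNA", "AGLCNA", "GLCNAC",
    "MAN", "AMAN", "BMAN", "BMA",
    "GAL", "BGAL", "AGAL", "GLA",
    "FUC", "AFUC", "BFUC",
    "NEU5AC", "ANE5AC", "SIA",
    "GLC", "AGLC", "BGLC",
    "XYL", "AXYL", "BXYL",
]

GPI_RESIDUES = ["DSPI", "SAPI", "GLCN", "PETN"]

SOLVENT = ["TIP3", "TIP3P", "TIP4", "TIP4P", "SPC", "SPCE", "SOL", "HOH", "WAT"]

IONS = ["NA", "CL", "K", "CA", "MG", "ZN", "SOD", "CLA", "POT", "CAL", "CES", "LIT"]

MOIETY_CLASSES = ("amino-acid", "glycan", "gpi", "lipid", "solvent", "ion")

DEFAULT_MOIETY_RULES: dict[str, str] = {}
for _names, _cls in (
    (AMINO_ACIDS, "amino-acid"),
    (LIPIDS, "lipid"),
    (GLYCANS, "glycan"),
    (GPI_RESIDUES, "gpi"),
    (SOLVENT, "solvent"),
    (IONS, "ion"),
):
    for _n in _names:
        DEFAULT_MOIETY_RULES[_n] = _cls


#: Lipid residue name -> headgroup chemical class used in contact reports.
DEFAULT_LIPID_CLASSES: dict[str, str] = {
    "CHL1": "cholesterol", "CHOL": "cholesterol", "ERG": "cholesterol",
    "PSM": "sphingomyelin", "SSM": "sphingomyelin", "NSM": "sphingomyelin",
    "LSM": "sphingomyelin", "DPSM": "sphingomyelin",
    "POPC": "phosphatidylcholine", "DPPC": "phosphatidylcholine",
    "DOPC": "phosphatidylcholine", "DSPC": "phosphatidylcholine",
    "DMPC": "phosphatidylcholine", "DLPC": "phosphatidylcholine",
    "POPE": "phosphatidylethanolamine", "DOPE": "phosphatidylethanolamine",
    "DPPE": "phosphatidylethanolamine",
    "POPI": "phosphatidylinositol", "DSPI": "phosphatidylinositol",
    "SAPI": "phosphatidylinositol",
}


def classify_residues(resnames, rules: dict[str, str] | None = None) -> list[str]:
    """Map residue names to moiety classes.

    Parameters
    ----------
    resnames
        Iterable of residue names (one per atom or per residue).
    rules
        Extra/overriding ``{resname: moiety-class}`` entries merged over the
        shipped defaults.

    Raises
    ------
    KeyError
        If any residue name has no rule; the message lists all offenders.
    """
    table = dict(DEFAULT_MOIETY_RULES)
    if rules:
        for name, cls in rules.items():
            if cls not in MOIETY_CLASSES:
                raise ValueError(
                    f"unknown moiety class {cls!r} for residue {name!r}; "
                    f"expected one of {MOIETY_CLASSES}"
                )
            table[name.upper()] = cls
    out = []
    unknown: set[str] = set()
    for rn in resnames:
        cls = table.get(str(rn).upper())
        if cls is None:
            unknown.add(str(rn))
        out.append(cls)
    if unknown:
        raise KeyError(
            "no moiety rule for residue name(s): "
            + ", ".join(sorted(unknown))
            + "; pass moiety_rules={'NAME': 'lipid'|'amino-acid'|...} to classify them"
        )
    return out


def lipid_class(resname: str, overrides: dict[str, str] | None = None) -> str:
    """Chemical class of a lipid residue for contact bookkeeping."""
    table = dict(DEFAULT_LIPID_CLASSES)
    if overrides:
        table.update({k.upper(): v for k, v in overrides.items()})
    return table.get(resname.upper(), "other")
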