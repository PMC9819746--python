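"""Typed protein-moiety/lipid contacts and their relative lifetimes.

Five contact types are detected per frame between protein-side residues
(amino acids, glycans, GPI residues) and membrane lipids:

``ionic``
    Any atom of a charged group within ``ionic`` cutoff of any atom of an
    oppositely charged group (salt bridge); counted per group pair.
``ion_dipole``
    A charged-group atom within ``ion_dipole`` cutoff of a *neutral* polar
    heavy atom (O/N outside charged groups); counted per (group, partner
    residue) pair, in both directions.
``hbond``
    Donor-acceptor heavy-atom distance <= ``hbond_da`` with the H-donor-
    acceptor angle <= ``hbond_angle``; counted per donor-acceptor pair.
``pication``
    A cation nitrogen/guanidinium centre within ``pication_dist`` of an
    aromatic ring centroid and within ``pication_angle`` of the ring normal.
``hydrophobic``
    A pair of positive-MHP (lipophilic) heavy atoms within ``hydrophobic``
    cutoff; counted per atom pair, following the molecular hydrophobic
    potential picture with a shipped, swappable atomic-constant table.

The *relative lifetime* of a (residue, lipid class, type) key is the sum of
its per-frame counts divided by the number of frames: 0 means never, 1 means
one contact throughout, and >1 means several simultaneous partners.

The report mirrors the field's table conventions: residues are listed in one
of four columns (ionic + ion-dipole, hydrogen bonds, pi-cation, hydrophobic)
with inclusion thresholds of 10% / 10% / 5% of the trajectory and, for the
hydrophobic column, at least two simultaneous contacts with a total lifetime
above 200%; each residue appears in exactly one column (ionic wins over
hbond, hbond over pi-cation, anything over hydrophobic), and polar entries
are emphasised at >= 50% (bold) and >= 75% (bold + underline) lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Topology
from .moieties import lipid_class as _lipid_class_of

__all__ = [
    "ContactCriteria", "ReportThresholds", "ContactTimelineSet",
    "ContactReport", "ReportEntry", "SystemAnnotations",
    "annotate_system", "detect_contacts", "lifetimes", "contact_report",
    "count_polar_residues", "contact_survey",
]

PROTEIN_MOIETIES = ("amino-acid", "glycan", "gpi")
POLAR_TYPES = ("ionic", "ion_dipole", "hbond")

AA_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_CANONICAL_AA = {"HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "HID": "HIS",
                 "HIE": "HIS", "HIP": "HIS", "CYX": "CYS", "ASH": "ASP",
                 "GLH": "GLU", "LYN": "LYS"}


@dataclass
class ContactCriteria:
    """Geometric contact criteria (nm, deg).  All configurable; defaults are
    standard MD-analysis conventions."""

    hbond_da: float = 0.35
    hbond_angle: float = 30.0
    ionic: float = 0.45
    ion_dipole: float = 0.40
    pication_dist: float = 0.60
    pication_angle: float = 45.0
    hydrophobic: float = 0.45
    mhp_table: str = "default"

    def __post_init__(self) -> None:
        for name in ("hbond_da", "ionic", "ion_dipole", "pication_dist",
                     "hydrophobic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle", "pication_angle"):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ValueError(f"{name} must be in (0, 180]")

    @classmethod
    def from_yaml(cls, path) -> "ContactCriteria":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ReportThresholds:
    polar: float = 0.10
    pication: float = 0.05
    hydrophobic_lifetime: float = 2.0
    hydrophobic_min_simultaneous: int = 2
    bold: float = 0.50
    underline: float = 0.75


# ---------------------------------------------------------------------------
# chemical annotation tables
# ---------------------------------------------------------------------------

# amino-acid charged groups (CHARMM-style protonation: Lys/Arg charged,
# Asp/Glu charged, His neutral)
_AA_CHARGED = {
    "LYS": [(+1, ("NZ",))],
    "ARG": [(+1, ("NE", "CZ", "NH1", "NH2"))],
    "ASP": [(-1, ("CG", "OD1", "OD2"))],
    "GLU": [(-1, ("CD", "OE1", "OE2"))],
}

# donor heavy atom -> possible hydrogen names (a donor is active only if at
# least one of its hydrogens exists in the topology)
_AA_DONORS = {
    "SER": {"OG": ("HG1", "HG")},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "TRP": {"NE1": ("HE1",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "CYS": {"SG": ("HG1", "HG")},
}
_BACKBONE_DONOR = {"N": ("H", "HN")}

_AA_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
_BACKBONE_ACCEPTOR = ("O", "OT1", "OT2", "OXT")

_AA_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

_AA_PI_CATIONS = {"LYS": ("NZ",), "ARG": ("CZ",)}

#: default atomic lipophilicity sign by element: carbons and sulfur carry
#: positive (lipophilic) constants, heteroatoms negative.  Swappable.
_MHP_TABLES = {
    "default": {"C": 0.36, "S": 0.10, "N": -0.60, "O": -0.40, "P": -0.70,
                "H": 0.0, "F": 0.2, "CL": 0.3},
}


def _is_phosphate_oxygen(name: str) -> bool:
    return name in ("O11", "O12", "O13", "O14", "OP1", "OP2", "OP3", "OP4",
                    "O1P", "O2P", "O3P", "O4P")


@dataclass
class _ChargedGroup:
    resnum: int
    sign: int
    atoms: np.ndarray


@dataclass
class _Ring:
    resnum: int
    atoms: np.ndarray


@dataclass
class _ResidueSide:
    """Annotation of one side (protein residues or lipid residues)."""

    charged_groups: list[_ChargedGroup] = field(default_factory=list)
    donors: list[tuple[int, int, int]] = field(default_factory=list)  # res, D, H
    acceptors: list[tuple[int, int]] = field(default_factory=list)    # res, atom
    polar: list[tuple[int, int]] = field(default_factory=list)        # neutral O/N
    rings: list[_Ring] = field(default_factory=list)
    cations: list[tuple[int, int]] = field(default_factory=list)      # res, atom
    mhp_pos: list[tuple[int, int]] = field(default_factory=list)      # res, atom


@dataclass
class SystemAnnotations:
    """Per-system chemical annotation derived from residue + atom names."""

    protein: _ResidueSide
    lipid: _ResidueSide
    residue_moiety: dict[int, str]
    residue_label: dict[int, str]
    lipid_class: dict[int, str]


def residue_label(resname: str, resnum: int, moiety: str) -> str:
    """Table-style residue label: K59 for amino acids, GlcN-2 style otherwise."""
    if moiety == "amino-acid":
        canon = _CANONICAL_AA.get(resname.upper(), resname.upper())
        one = AA_ONE_LETTER.get(canon)
        if one:
            return f"{one}{resnum}"
    return f"{resname}-{resnum}"


def _annotate_amino_acid(resname, resnum, names, idx, have, side: _ResidueSide,
                         mhp, strict: bool) -> None:
    canon = _CANONICAL_AA.get(resname, resname)
    if canon not in AA_ONE_LETTER:
        if strict:
            raise KeyError(f"no annotation table for amino-acid residue {resname!r}")
        return
    for sign, group in _AA_CHARGED.get(canon, []):
        atoms = [have[a] for a in group if a in have]
        if atoms:
            side.charged_groups.append(_ChargedGroup(resnum, sign, np.array(atoms)))
    charged_atoms = {a for _s, grp in _AA_CHARGED.get(canon, []) for a in grp}
    donors = dict(_BACKBONE_DONOR)
    donors.update(_AA_DONORS.get(canon, {}))
    for heavy, hyds in donors.items():
        if heavy not in have:
            continue
        for h in hyds:
            if h in have:
                side.donors.append((resnum, have[heavy], have[h]))
                break
    for acc in (*_BACKBONE_ACCEPTOR, *_AA_ACCEPTORS.get(canon, ())):
        if acc in have:
            side.acceptors.append((resnum, have[acc]))
    for ring in _AA_RINGS.get(canon, []):
        atoms = [have[a] for a in ring if a in have]
        if len(atoms) == len(ring):
            side.rings.append(_Ring(resnum, np.array(atoms)))
    for cat in _AA_PI_CATIONS.get(canon, ()):
        if cat in have:
            side.cations.append((resnum, have[cat]))
    for nm, i in have.items():
        el = names[1][i]
        if el in ("O", "N") and nm not in charged_atoms:
            side.polar.append((resnum, i))
        if mhp.get(el, 0.0) > 0:
            side.mhp_pos.append((resnum, i))


def _annotate_sugarlike(resnum, have, elements, side: _ResidueSide, mhp) -> None:
    """Generic carbohydrate / GPI-residue rules: oxygens are acceptors and
    polar; hydroxyl H's (if present) make their oxygen a donor; phosphates
    are anionic; amines cationic."""
    phosphate = [i for nm, i in have.items()
                 if elements[i] == "P" or _is_phosphate_oxygen(nm)]
    if phosphate:
        side.charged_groups.append(_ChargedGroup(resnum, -1, np.array(phosphate)))
    for nm, i in have.items():
        el = elements[i]
        if el == "O" and i not in phosphate:
            side.acceptors.append((resnum, i))
            side.polar.append((resnum, i))
            for hname, hi in have.items():
                if elements[hi] == "H" and hname[1:] == nm[1:] and hname != nm:
                    side.donors.append((resnum, i, hi))
                    break
        elif el == "N":
            side.polar.append((resnum, i))
        if mhp.get(el, 0.0) > 0:
            side.mhp_pos.append((resnum, i))


def _annotate_lipid(resnum, have, elements, side: _ResidueSide, mhp) -> None:
    """Generic headgroup rules: P + phosphate oxygens anionic, the headgroup
    nitrogen cationic (choline/ethanolamine), remaining O neutral polar
    acceptors, carbons lipophilic."""
    phosphate = [i for nm, i in have.items()
                 if elements[i] == "P" or _is_phosphate_oxygen(nm)]
    if phosphate:
        side.charged_groups.append(_ChargedGroup(resnum, -1, np.array(phosphate)))
    for nm, i in have.items():
        el = elements[i]
        if el == "N":
            side.charged_groups.append(_ChargedGroup(resnum, +1, np.array([i])))
            side.cations.append((resnum, i))
        elif el == "O":
            side.acceptors.append((resnum, i))
            if i not in phosphate:
                side.polar.append((resnum, i))
        if mhp.get(el, 0.0) > 0:
            side.mhp_pos.append((resnum, i))


def annotate_system(topology: Topology, criteria: ContactCriteria | None = None,
                    strict: bool = True,
                    glycan_kind: dict[int, str] | None = None) -> SystemAnnotations:
    """Derive donor/acceptor/charge/ring/MHP annotations from the topology.

    ``glycan_kind`` optionally refines glycan residues to ``"N-glycan"`` /
    ``"O-glycan"`` by residue number (the topology alone cannot tell them
    apart without connectivity).
    """
    criteria = criteria or ContactCriteria()
    mhp = _MHP_TABLES[criteria.mhp_table]
    protein = _ResidueSide()
    lipid = _ResidueSide()
    residue_moiety: dict[int, str] = {}
    labels: dict[int, str] = {}
    lclasses: dict[int, str] = {}
    names = (topology.names, topology.elements)
    for resnum in np.unique(topology.resnums):
        idx = topology.residue_atoms(int(resnum))
        moiety = str(topology.moieties[idx[0]])
        resname = str(topology.resnames[idx[0]]).upper()
        report_moiety = moiety
        if moiety == "glycan" and glycan_kind:
            kind = glycan_kind.get(int(resnum))
            if kind not in (None, "N", "O"):
                raise ValueError(f"glycan_kind for residue {resnum} must be 'N' or 'O'")
            if kind:
                report_moiety = f"{kind}-glycan"
        residue_moiety[int(resnum)] = report_moiety
        labels[int(resnum)] = residue_label(resname, int(resnum), moiety)
        have = {str(topology.names[i]): int(i) for i in idx}
        if moiety == "amino-acid":
            _annotate_amino_acid(resname, int(resnum), names, idx, have,
                                 protein, mhp, strict)
        elif moiety in ("glycan", "gpi"):
            _annotate_sugarlike(int(resnum), have, topology.elements, protein, mhp)
        elif moiety == "lipid":
            _annotate_lipid(int(resnum), have, topology.elements, lipid, mhp)
            lclasses[int(resnum)] = _lipid_class_of(resname)
    return SystemAnnotations(protein=protein, lipid=lipid,
                             residue_moiety=residue_moiety,
                             residue_label=labels, lipid_class=lclasses)


# ---------------------------------------------------------------------------
# per-frame detection
# ---------------------------------------------------------------------------

def _mindist(frame, a_idx, b_idx, box=None) -> float:
    d = frame[np.asarray(a_idx)][:, None, :] - frame[np.asarray(b_idx)][None, :, :]
    if box is not None:
        d -= np.round(d / box) * box
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def _dist(frame, i, j, box=None) -> float:
    d = frame[i] - frame[j]
    if box is not None:
        d -= np.round(d / box) * box
    return float(np.linalg.norm(d))


def detect_contacts(frame: np.ndarray, topology: Topology,
                    criteria: ContactCriteria,
                    ann: SystemAnnotations | None = None,
                    box: np.ndarray | None = None) -> dict:
    """Count qualifying contacts of each type in one frame.

    Returns ``{(residue_label, moiety, lipid_class, type): count}`` for
    protein-side residues against membrane lipids.
    """
    if ann is None:
        ann = annotate_system(topology, criteria)
    counts: dict[tuple, int] = {}

    def add(resnum: int, lipid_resnum: int, ctype: str, n: int = 1) -> None:
        key = (ann.residue_label[resnum], ann.residue_moiety[resnum],
               ann.lipid_class[lipid_resnum], ctype)
        counts[key] = counts.get(key, 0) + n

    # ionic: opposite charged groups
    for pg in ann.protein.charged_groups:
        for lg in ann.lipid.charged_groups:
            if pg.sign * lg.sign >= 0:
                continue
            if _mindist(frame, pg.atoms, lg.atoms, box) <= criteria.ionic:
                add(pg.resnum, lg.resnum, "ionic")

    # ion-dipole: charged group <-> neutral polar atoms of the other side
    lipid_polar_by_res: dict[int, list[int]] = {}
    for rn, i in ann.lipid.polar:
        lipid_polar_by_res.setdefault(rn, []).append(i)
    for pg in ann.protein.charged_groups:
        for rn, atoms in lipid_polar_by_res.items():
            if _mindist(frame, pg.atoms, atoms, box) <= criteria.ion_dipole:
                add(pg.resnum, rn, "ion_dipole")
    protein_polar_by_res: dict[int, list[int]] = {}
    for rn, i in ann.protein.polar:
        protein_polar_by_res.setdefault(rn, []).append(i)
    for lg in ann.lipid.charged_groups:
        for rn, atoms in protein_polar_by_res.items():
            if _mindist(frame, lg.atoms, atoms, box) <= criteria.ion_dipole:
                add(rn, lg.resnum, "ion_dipole")

    # hydrogen bonds, both directions
    def hbond_pairs(donors, acceptors, key_from_donor: bool):
        for rn_d, d_i, h_i in donors:
            for rn_a, a_i in acceptors:
                if _dist(frame, d_i, a_i, box) > criteria.hbond_da:
                    continue
                vh = frame[h_i] - frame[d_i]
                va = frame[a_i] - frame[d_i]
                if box is not None:
                    vh -= np.round(vh / box) * box
                    va -= np.round(va / box) * box
                cosang = np.dot(vh, va) / (np.linalg.norm(vh) * np.linalg.norm(va))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang <= criteria.hbond_angle:
                    if key_from_donor:
                        add(rn_d, rn_a, "hbond")
                    else:
                        add(rn_a, rn_d, "hbond")

    hbond_pairs(ann.protein.donors, ann.lipid.acceptors, True)
    hbond_pairs(ann.lipid.donors, ann.protein.acceptors, False)

    # pi-cation: protein rings x lipid cations (and protein cations x lipid rings)
    def pication_pairs(rings, cations, key_from_ring: bool):
        for ring in rings:
            pts = frame[ring.atoms]
            centroid = pts.mean(axis=0)
            normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            normal /= np.linalg.norm(normal)
            for rn_c, c_i in cations:
                v = frame[c_i] - centroid
                if box is not None:
                    v -= np.round(v / box) * box
                dist = float(np.linalg.norm(v))
                if dist > criteria.pication_dist or dist == 0:
                    continue
                cosang = abs(np.dot(v / dist, normal))
                ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
                if ang <= criteria.pication_angle:
                    if key_from_ring:
                        add(ring.resnum, rn_c, "pication")
                    else:
                        add(rn_c, ring.resnum, "pication")

    pication_pairs(ann.protein.rings, ann.lipid.cations, True)
    pication_pairs(ann.lipid.rings, ann.protein.cations, False)

    # hydrophobic: positive-MHP atom pairs
    if ann.protein.mhp_pos and ann.lipid.mhp_pos:
        p_res = np.array([rn for rn, _ in ann.protein.mhp_pos])
        p_idx = np.array([i for _, i in ann.protein.mhp_pos])
        l_res = np.array([rn for rn, _ in ann.lipid.mhp_pos])
        l_idx = np.array([i for _, i in ann.lipid.mhp_pos])
        d = frame[p_idx][:, None, :] - frame[l_idx][None, :, :]
        if box is not None:
            d -= np.round(d / box) * box
        dist = np.sqrt((d ** 2).sum(axis=2))
        pi, li = np.nonzero(dist <= criteria.hydrophobic)
        for a, b in zip(pi, li):
            add(int(p_res[a]), int(l_res[b]), "hydrophobic")
    return counts


# ---------------------------------------------------------------------------
# lifetimes and report
# ---------------------------------------------------------------------------

@dataclass
class ContactTimelineSet:
    """Relative lifetimes per (residue, moiety, lipid class, type) key.

    ``lipid_class == "all"`` rows aggregate over lipid classes; ``max_count``
    is the largest simultaneous contact count seen in any frame.
    """

    records: "object"   # pandas DataFrame
    n_frames: int

    def lifetime(self, label: str, ctype: str, lipid_class: str = "all") -> float:
        df = self.records
        m = ((df["residue"] == label) & (df["type"] == ctype)
             & (df["lipid_class"] == lipid_class))
        return float(df.loc[m, "lifetime"].sum())

    @classmethod
    def from_records(cls, rows: list[dict], n_frames: int) -> "ContactTimelineSet":
        """Build a timeline set from explicit lifetime rows (fixtures).

        Rows without a ``lipid_class`` are taken as the all-lipid aggregate;
        ``max_count`` defaults to 1.
        """
        import pandas as pd

        norm = []
        for r in rows:
            norm.append({
                "residue": r["residue"], "moiety": r.get("moiety", "amino-acid"),
                "lipid_class": r.get("lipid_class", "all"), "type": r["type"],
                "lifetime": float(r["lifetime"]),
                "max_count": int(r.get("max_count", 1)),
            })
        return cls(records=pd.DataFrame(norm, columns=[
            "residue", "moiety", "lipid_class", "type", "lifetime",
            "max_count"]), n_frames=n_frames)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def lifetimes(per_frame_counts: list[dict], n_frames: int | None = None
              ) -> ContactTimelineSet:
    """Accumulate per-frame counts into relative lifetimes.

    ``relative lifetime = sum of per-frame counts / n_frames``; an "all"
    lipid-class aggregate is added for every (residue, type).
    """
    import pandas as pd

    if n_frames is None:
        n_frames = len(per_frame_counts)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    totals: dict[tuple, float] = {}
    max_count: dict[tuple, int] = {}
    for counts in per_frame_counts:
        agg: dict[tuple, int] = {}
        for (label, moiety, lclass, ctype), n in counts.items():
            for key in ((label, moiety, lclass, ctype),
                        (label, moiety, "all", ctype)):
                agg[key] = agg.get(key, 0) + n
        for key, n in agg.items():
            totals[key] = totals.get(key, 0.0) + n
            max_count[key] = max(max_count.get(key, 0), n)
    rows = [{
        "residue": k[0], "moiety": k[1], "lipid_class": k[2], "type": k[3],
        "lifetime": totals[k] / n_frames, "max_count": max_count[k],
    } for k in sorted(totals)]
    df = pd.DataFrame(rows, columns=["residue", "moiety", "lipid_class",
                                     "type", "lifetime", "max_count"])
    return ContactTimelineSet(records=df, n_frames=n_frames)


@dataclass
class ReportEntry:
    residue: str
    moiety: str
    column: str     # ionic | hbond | pication | hydrophobic
    tier: str       # plain | bold | bold_underline
    lifetime: float


@dataclass
class ContactReport:
    label: str
    entries: list[ReportEntry]

    def column(self, name: str) -> list[ReportEntry]:
        return [e for e in self.entries if e.column == name]

    def to_markdown(self) -> str:
        headers = {"ionic": "Ion-ion and ion-dipole", "hbond": "Hydrogen bonds",
                   "pication": "Pi-cation", "hydrophobic": "Hydrophobic"}
        lines = [f"## {self.label}", ""]
        for col, title in headers.items():
            cells = []
            for e in self.column(col):
                text = e.residue
                if e.tier == "bold":
                    text = f"**{text}**"
                elif e.tier == "bold_underline":
                    text = f"**<u>{text}</u>**"
                cells.append(text)
            lines.append(f"- {title}: " + (", ".join(cells) if cells else "-"))
        return "\n".join(lines)


def contact_report(timelines: ContactTimelineSet,
                   thresholds: ReportThresholds | None = None,
                   label: str = "") -> ContactReport:
    """Render the four-column residue report with precedence and emphasis.

    Inclusion: ionic + ion-dipole lifetime >= ``polar`` puts a residue in the
    ionic column; otherwise hbond lifetime >= ``polar`` -> hbond column;
    otherwise pi-cation lifetime >= ``pication`` -> pi-cation column;
    otherwise hydrophobic total > ``hydrophobic_lifetime`` with at least
    ``hydrophobic_min_simultaneous`` simultaneous pairs -> hydrophobic
    column.  Polar columns are emphasised by their own lifetime: bold at
    >= 0.5, bold + underline at >= 0.75.
    """
    th = thresholds or ReportThresholds()
    df = timelines.records
    all_rows = df[df["lipid_class"] == "all"]
    if all_rows.empty and not df.empty:
        all_rows = df
    entries: list[ReportEntry] = []
    residues = all_rows[["residue", "moiety"]].drop_duplicates().values.tolist()
    for residue, moiety in residues:
        sub = all_rows[(all_rows["residue"] == residue)
                       & (all_rows["moiety"] == moiety)]
        lt = {t: float(sub.loc[sub["type"] == t, "lifetime"].sum())
              for t in ("ionic", "ion_dipole", "hbond", "pication", "hydrophobic")}
        hydro_max = int(sub.loc[sub["type"] == "hydrophobic", "max_count"].max()) \
            if (sub["type"] == "hydrophobic").any() else 0
        ionic_total = lt["ionic"] + lt["ion_dipole"]
        if ionic_total >= th.polar:
            column, basis = "ionic", ionic_total
        elif lt["hbond"] >= th.polar:
            column, basis = "hbond", lt["hbond"]
        elif lt["pication"] >= th.pication:
            column, basis = "pication", lt["pication"]
        elif (lt["hydrophobic"] > th.hydrophobic_lifetime
              and hydro_max >= th.hydrophobic_min_simultaneous):
            column, basis = "hydrophobic", lt["hydrophobic"]
        else:
            continue
        if column in ("ionic", "hbond") and basis >= th.underline:
            tier = "bold_underline"
        elif column in ("ionic", "hbond") and basis >= th.bold:
            tier = "bold"
        else:
            tier = "plain"
        entries.append(ReportEntry(residue=residue, moiety=moiety, column=column,
                                   tier=tier, lifetime=basis))
    order = {"ionic": 0, "hbond": 1, "pication": 2, "hydrophobic": 3}
    entries.sort(key=lambda e: (order[e.column], e.residue))
    return ContactReport(label=label, entries=entries)


def count_polar_residues(report: ContactReport, moiety: str = "amino-acid") -> int:
    """Distinct residues of a moiety listed in the ionic or hbond columns."""
    return len({e.residue for e in report.entries
                if e.moiety == moiety and e.column in ("ionic", "hbond")})


def contact_survey(traj, criteria: ContactCriteria | None = None,
                   stride: int = 1) -> ContactTimelineSet:
    """Detect contacts over a trajectory and accumulate lifetimes."""
    criteria = criteria or ContactCriteria()
    ann = annotate_system(traj.topology, criteria)
    frames = range(0, traj.n_frames, stride)
    per_frame = [detect_contacts(traj.coords[i], traj.topology, criteria,
                                 ann, box=traj.boxes[i])
                 for i in frames]
    return lifetimes(per_frame, len(per_frame))
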