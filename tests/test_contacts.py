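import numpy as np
import pytest

from ly6orient.contacts import (
    ContactCriteria, ContactTimelineSet, ReportThresholds, annotate_system,
    contact_report, contact_survey, count_polar_residues, detect_contacts,
    lifetimes,
)
from ly6orient.io_core import Topology
from ly6orient.synthetic import generate_trajectory, plant_contacts


def _mini_system(protein_atoms, lipid_atoms):
    """Build a toy topology + frame: one protein residue, one POPC lipid.

    ``protein_atoms``: list of (resname, resnum, name, element, xyz).
    """
    rows = list(protein_atoms) + [
        ("POPC", 100, name, el, xyz) for name, el, xyz in lipid_atoms]
    top = Topology(
        names=np.array([r[2] for r in rows], dtype=object),
        elements=np.array([r[3] for r in rows], dtype=object),
        masses=np.array([{"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008,
                          "P": 30.974}[r[3]] for r in rows]),
        resnames=np.array([r[0] for r in rows], dtype=object),
        resnums=np.array([r[1] for r in rows], dtype=int),
        chains=np.array([""] * len(rows), dtype=object),
        moieties=np.array(["amino-acid" if r[0] not in ("POPC",) else "lipid"
                           for r in rows], dtype=object),
    )
    frame = np.array([r[4] for r in rows], dtype=float)
    return top, frame


class TestDetection:
    def test_lys_ionic_contact(self):
        """Lys NZ 0.30 nm from a lipid phosphate: one ionic contact."""
        top, frame = _mini_system(
            [("LYS", 57, "CA", "C", (0, 0, 1.0)), ("LYS", 57, "NZ", "N", (0, 0, 0.30))],
            [("P", "P", (0, 0, 0.0)), ("O2", "O", (0, 0, -0.8))],
        )
        counts = detect_contacts(frame, top, ContactCriteria())
        assert counts[("K57", "amino-acid", "phosphatidylcholine", "ionic")] == 1

    def test_tyr_hydrogen_bond_geometry(self):
        """OH donor, D-A 0.30 nm, H-D-A angle 10 deg: one hydrogen bond."""
        ang = np.radians(10.0)
        top, frame = _mini_system(
            [("TYR", 53, "OH", "O", (0, 0, 0.30)),
             ("TYR", 53, "HH", "H", (0.1 * np.sin(ang), 0, 0.30 - 0.1 * np.cos(ang)))],
            [("O2", "O", (0, 0, 0.0)), ("C21", "C", (0, 0, -2.0))],
        )
        counts = detect_contacts(frame, top, ContactCriteria())
        assert counts[("Y53", "amino-acid", "phosphatidylcholine", "hbond")] == 1

    def test_hbond_rejected_by_angle(self):
        top, frame = _mini_system(
            [("TYR", 53, "OH", "O", (0, 0, 0.30)),
             ("TYR", 53, "HH", "H", (0.098, 0, 0.32))],   # H points sideways
            [("O2", "O", (0, 0, 0.0))],
        )
        counts = detect_contacts(frame, top, ContactCriteria())
        assert ("Y53", "amino-acid", "phosphatidylcholine", "hbond") not in counts

    def test_beyond_all_cutoffs_no_contacts(self):
        """Arg guanidinium 0.9 nm from any lipid atom: nothing detected."""
        top, frame = _mini_system(
            [("ARG", 38, "CZ", "C", (0, 0, 0.9)), ("ARG", 38, "NH1", "N", (0.1, 0, 0.95)),
             ("ARG", 38, "NH2", "N", (-0.1, 0, 0.95)), ("ARG", 38, "NE", "N", (0, 0.1, 0.95))],
            [("P", "P", (0, 0, 0.0)), ("N", "N", (0, 0, 0.2)),
             ("O2", "O", (0, 0, -0.15)), ("C21", "C", (0, 0, -0.6))],
        )
        assert detect_contacts(frame, top, ContactCriteria()) == {}

    def test_pication_geometry(self):
        """Choline N on the ring axis at 0.45 nm: one pi-cation contact."""
        ring = []
        for k, nm in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            a = np.radians(60.0 * k)
            ring.append(("PHE", 67, nm, "C", (0.14 * np.cos(a), 0.14 * np.sin(a), 0.0)))
        top, frame = _mini_system(
            ring, [("N", "N", (0, 0, -0.45)), ("P", "P", (0, 0, -1.2))])
        counts = detect_contacts(frame, top, ContactCriteria())
        assert counts[("F67", "amino-acid", "phosphatidylcholine", "pication")] == 1

    def test_hydrophobic_pair_counting(self):
        """Each positive-MHP atom pair within 0.45 nm counts separately."""
        top, frame = _mini_system(
            [("LEU", 10, "CD1", "C", (0, 0, 0.30)), ("LEU", 10, "CD2", "C", (0.2, 0, 0.30))],
            [("C21", "C", (0, 0, 0.0)), ("C31", "C", (0.2, 0, 0.0))],
        )
        counts = detect_contacts(frame, top, ContactCriteria())
        # all four pairs are within sqrt(0.2^2+0.3^2) = 0.36 nm
        assert counts[("L10", "amino-acid", "phosphatidylcholine", "hydrophobic")] == 4

    def test_glycan_kind_refines_moiety_labels(self):
        top, _frame = _mini_system(
            [("LYS", 57, "NZ", "N", (0, 0, 0.3))],
            [("P", "P", (0, 0, 0.0))])
        top.resnames[:1] = "NAG"
        top.moieties[:1] = "glycan"
        ann = annotate_system(top, glycan_kind={57: "N"})
        assert ann.residue_moiety[57] == "N-glycan"
        with pytest.raises(ValueError, match="glycan_kind"):
            annotate_system(top, glycan_kind={57: "Q"})

    def test_detection_is_deterministic(self, calm_spec):
        traj, truth = generate_trajectory(calm_spec(n_frames=30, seed=5))
        plant_contacts(traj, truth, [(7, "ionic", 0.5)], seed=2)
        crit = ContactCriteria()
        ann = annotate_system(traj.topology, crit)
        a = detect_contacts(traj.coords[3], traj.topology, crit, ann, traj.boxes[3])
        b = detect_contacts(traj.coords[3], traj.topology, crit, ann, traj.boxes[3])
        assert a == b


class TestLifetimes:
    def test_relative_lifetime_definition(self):
        key = ("R57", "amino-acid", "phosphatidylcholine", "ionic")
        frames = [{key: 1} if i < 300 else {} for i in range(1000)]
        tl = lifetimes(frames, 1000)
        assert tl.lifetime("R57", "ionic") == pytest.approx(0.30)

    def test_simultaneous_contacts_exceed_one(self):
        key = ("K59", "amino-acid", "phosphatidylcholine", "ionic")
        tl = lifetimes([{key: 2} for _ in range(100)], 100)
        assert tl.lifetime("K59", "ionic") == pytest.approx(2.0)
        row = tl.records[(tl.records.residue == "K59")
                         & (tl.records.lipid_class == "all")]
        assert int(row["max_count"].iloc[0]) == 2

    def test_no_contacts_empty(self):
        tl = lifetimes([{} for _ in range(10)], 10)
        assert tl.records.empty
        assert tl.lifetime("K59", "ionic") == 0.0

    def test_per_class_and_total_aggregation(self):
        k1 = ("K59", "amino-acid", "phosphatidylcholine", "ionic")
        k2 = ("K59", "amino-acid", "cholesterol", "ionic")
        tl = lifetimes([{k1: 1, k2: 1} for _ in range(10)], 10)
        assert tl.lifetime("K59", "ionic", "phosphatidylcholine") == 1.0
        assert tl.lifetime("K59", "ionic", "cholesterol") == 1.0
        assert tl.lifetime("K59", "ionic", "all") == 2.0

    def test_monotone_in_cutoffs(self, calm_spec):
        """Enlarging every distance cutoff never decreases any lifetime."""
        traj, truth = generate_trajectory(calm_spec(n_frames=40, seed=8))
        plant_contacts(traj, truth, [(7, "ionic", 0.5), (8, "hbond", 0.3)], seed=4)
        tight = contact_survey(traj, ContactCriteria())
        loose = contact_survey(traj, ContactCriteria(
            hbond_da=0.45, ionic=0.60, ion_dipole=0.55, pication_dist=0.80,
            hydrophobic=0.60))
        for _, row in tight.records.iterrows():
            lt_loose = loose.lifetime(row["residue"], row["type"], row["lipid_class"])
            assert lt_loose >= row["lifetime"] - 1e-12


LYNX1_ROWS = [
    # ionic + ion-dipole column (Table-style fixture: bold -> 0.6, plain -> 0.3)
    *[{"residue": r, "type": "ionic", "lifetime": lt}
      for r, lt in [("D31", 0.3), ("R38", 0.3), ("R57", 0.6), ("K59", 0.6)]],
    *[{"residue": r, "moiety": "gpi", "type": "ionic", "lifetime": lt}
      for r, lt in [("DSPI-1", 0.6), ("GlcN-2", 0.3), ("PEtN-Man-3", 0.6)]],
    # hydrogen-bond column
    *[{"residue": r, "type": "hbond", "lifetime": lt}
      for r, lt in [("Y28", 0.3), ("N29", 0.3), ("G30", 0.3), ("N32", 0.6),
                    ("C33", 0.3), ("F34", 0.3), ("N35", 0.6), ("Y53", 0.6),
                    ("T54", 0.3), ("T56", 0.3), ("Y76", 0.3)]],
    # hydrophobic column (>= 2 simultaneous, total > 200%)
    *[{"residue": r, "type": "hydrophobic", "lifetime": 2.5, "max_count": 3}
      for r in ["C26", "A27", "P36", "P55"]],
]


class TestReport:
    def test_precedence_ionic_over_hbond(self):
        tl = ContactTimelineSet.from_records([
            {"residue": "R57", "type": "ionic", "lifetime": 0.6},
            {"residue": "R57", "type": "hbond", "lifetime": 0.3},
        ], 1000)
        rep = contact_report(tl)
        assert [ (e.residue, e.column, e.tier) for e in rep.entries ] == \
            [("R57", "ionic", "bold")]

    def test_hydrophobic_below_200_percent_omitted(self):
        tl = ContactTimelineSet.from_records([
            {"residue": "P55", "type": "hydrophobic", "lifetime": 1.5,
             "max_count": 3},
        ], 1000)
        assert contact_report(tl).entries == []

    def test_hydrophobic_needs_two_simultaneous(self):
        tl = ContactTimelineSet.from_records([
            {"residue": "P55", "type": "hydrophobic", "lifetime": 2.5,
             "max_count": 1},
        ], 1000)
        assert contact_report(tl).entries == []

    def test_pication_between_5_and_50_percent_plain(self):
        tl = ContactTimelineSet.from_records([
            {"residue": "F31", "type": "pication", "lifetime": 0.06},
        ], 1000)
        rep = contact_report(tl)
        assert [(e.residue, e.column, e.tier) for e in rep.entries] == \
            [("F31", "pication", "plain")]

    def test_emphasis_tiers(self):
        tl = ContactTimelineSet.from_records([
            {"residue": "A1", "type": "ionic", "lifetime": 0.30},
            {"residue": "A2", "type": "ionic", "lifetime": 0.55},
            {"residue": "A3", "type": "ionic", "lifetime": 0.80},
            {"residue": "A4", "type": "ionic", "lifetime": 0.05},
        ], 1000)
        rep = contact_report(tl)
        tiers = {e.residue: e.tier for e in rep.entries}
        assert tiers == {"A1": "plain", "A2": "bold", "A3": "bold_underline"}

    def test_no_residue_in_two_columns(self):
        """Randomised lifetime sets never place a residue in two columns."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            rows = []
            for i in range(12):
                for t in ("ionic", "ion_dipole", "hbond", "pication", "hydrophobic"):
                    if rng.random() < 0.6:
                        rows.append({"residue": f"X{i}", "type": t,
                                     "lifetime": float(rng.uniform(0, 3)),
                                     "max_count": int(rng.integers(1, 5))})
            rep = contact_report(ContactTimelineSet.from_records(rows, 100))
            seen = [e.residue for e in rep.entries]
            assert len(seen) == len(set(seen))

    def test_lynx1_fixture_15_polar_residues(self):
        """The encoded Lynx1 table rows yield 15 distinct amino-acid residues
        in the polar (ionic + hydrogen-bond) columns."""
        tl = ContactTimelineSet.from_records(LYNX1_ROWS, 2000)
        rep = contact_report(tl, label="Lynx1")
        assert count_polar_residues(rep) == 15
        assert len(rep.column("ionic")) == 7       # 4 amino acids + 3 GPI
        assert len(rep.column("hbond")) == 11
        assert len(rep.column("hydrophobic")) == 4
        md = rep.to_markdown()
        assert "**R57**" in md and "Y76" in md

    def test_empty_and_gpi_only_reports(self):
        assert count_polar_residues(
            contact_report(ContactTimelineSet.from_records([], 10))) == 0
        tl = ContactTimelineSet.from_records([
            {"residue": "DSPI-1", "moiety": "gpi", "type": "ionic",
             "lifetime": 0.9}], 10)
        assert count_polar_residues(contact_report(tl)) == 0


class TestPlantedRecovery:
    def test_lifetimes_match_planted_fractions_exactly(self, calm_spec):
        traj, truth = generate_trajectory(calm_spec(n_frames=200, seed=5))
        plan = [(7, "ionic", 0.40), (8, "hbond", 0.25), (9, "pication", 0.10)]
        plant_contacts(traj, truth, plan, seed=6)
        tl = contact_survey(traj)
        assert tl.lifetime("K7", "ionic") == pytest.approx(0.40, abs=1e-12)
        assert tl.lifetime("Y8", "hbond") == pytest.approx(0.25, abs=1e-12)
        assert tl.lifetime("F9", "pication") == pytest.approx(0.10, abs=1e-12)
        # nothing else was detected
        assert len(tl.records[tl.records.lipid_class == "all"]) == 3
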