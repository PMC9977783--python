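"""Structural-water hydrogen-bond networks over structure ensembles.

A *structural water* is a water molecule whose oxygen lies within hydrogen-
bonding distance (heavy-atom <= 3.2 A, no angle term) of at least three
protein or ligand N/O atoms.  Within a ligand-binding pocket (6 A shell
around any ligand atom), the fraction of ensemble members in which a
residue hydrogen-bonds such a water estimates the probability that the
residue participates in a water-mediated network.  Water positions can be
matched between ensembles (e.g. predictions vs. crystallographic waters)
by greedy nearest-neighbour pairing at a distance tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Structure",
    "WaterContact",
    "WaterProbabilityMap",
    "read_ensemble",
    "write_ensemble_pdb",
    "water_contacts",
    "structural_waters",
    "pocket_filter",
    "hbond_probability",
    "match_waters",
    "match_positions",
]

WATER_RESNAMES = {"HOH", "WAT", "DOD"}
HBOND_ELEMENTS = {"N", "O"}

HBOND_CUTOFF_A = 3.2
POCKET_SHELL_A = 6.0
MIN_CONTACTS = 3
MATCH_TOLERANCE_A = 0.5


@dataclass
class Structure:
    """Flat atom table for one ensemble member.

    ``het`` marks HETATM records; waters are identified by residue name,
    the ligand is any non-water HETATM.  Residue keys are
    (chain, resseq, resname) so insertion-free numbering is preserved
    across structures.
    """

    xyz: np.ndarray         # (N, 3) Angstrom
    element: np.ndarray
    atom_name: np.ndarray
    resname: np.ndarray
    resseq: np.ndarray
    chain: np.ndarray
    het: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def water_mask(self) -> np.ndarray:
        return np.isin(self.resname, list(WATER_RESNAMES))

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.het & ~self.water_mask

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.water_mask & (self.element == "O"))

    def water_id(self, atom_index: int) -> tuple:
        return (str(self.chain[atom_index]), int(self.resseq[atom_index]))

    def residue_key(self, atom_index: int) -> tuple:
        return (
            str(self.chain[atom_index]),
            int(self.resseq[atom_index]),
            str(self.resname[atom_index]),
        )


@dataclass(frozen=True)
class WaterContact:
    """One heavy-atom hydrogen bond between a water oxygen and a partner."""

    water_id: tuple                 # (chain, resseq)
    partner_residue: tuple          # (chain, resseq, resname)
    partner_atom: str
    distance_a: float


def read_ensemble(path) -> list[Structure]:
    """Read a (multi-model) PDB file into an ensemble of structures.

    Alternate locations are resolved to the highest occupancy, ties broken
    alphabetically by altloc code.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    ensemble = []
    for model in st:
        rows = []
        for chain in model:
            for res in chain:
                # altloc resolution: keep the best conformer per atom name
                best: dict[str, object] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None or (atom.occ, -ord(atom.altloc or "~")) > (
                        prev.occ, -ord(prev.altloc or "~")
                    ):
                        best[atom.name] = atom
                for atom in best.values():
                    rows.append((
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                        atom.element.name.upper(),
                        atom.name,
                        res.name,
                        res.seqid.num,
                        chain.name,
                        res.het_flag == "H",
                    ))
        ensemble.append(Structure(
            xyz=np.array([r[0] for r in rows], dtype=float),
            element=np.array([r[1] for r in rows]),
            atom_name=np.array([r[2] for r in rows]),
            resname=np.array([r[3] for r in rows]),
            resseq=np.array([r[4] for r in rows], dtype=int),
            chain=np.array([r[5] for r in rows]),
            het=np.array([r[6] for r in rows], dtype=bool),
        ))
    return ensemble


def write_ensemble_pdb(ensemble: Sequence[Structure], path) -> None:
    """Write an ensemble as a multi-model PDB (waters HOH, ligand HETATM)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "ensemble"
    for mi, s in enumerate(ensemble, start=1):
        model = gemmi.Model(mi)
        chains: dict[str, gemmi.Chain] = {}
        for i in range(len(s.xyz)):
            cname = str(s.chain[i])
            if cname not in chains:
                chains[cname] = gemmi.Chain(cname)
            chain = chains[cname]
            resseq = int(s.resseq[i])
            if len(chain) == 0 or chain[-1].seqid.num != resseq or chain[-1].name != str(s.resname[i]):
                res = gemmi.Residue()
                res.name = str(s.resname[i])
                res.seqid = gemmi.SeqId(resseq, " ")
                res.het_flag = "H" if bool(s.het[i]) else "A"
                chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = str(s.atom_name[i])
            atom.element = gemmi.Element(str(s.element[i]))
            atom.pos = gemmi.Position(*s.xyz[i])
            atom.occ = 1.0
            chain[-1].add_atom(atom)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def water_contacts(structure: Structure, cutoff: float = HBOND_CUTOFF_A) -> list[WaterContact]:
    """All heavy-atom hydrogen bonds between water oxygens and protein/ligand.

    Partners are N and O atoms of non-water residues only (carbon and
    sulfur cannot accept/donate here; water-water pairs are excluded).
    The cutoff is inclusive.
    """
    w_idx = structure.water_oxygen_indices
    partner_mask = (
        ~structure.water_mask
        & np.isin(structure.element, list(HBOND_ELEMENTS))
    )
    p_idx = np.flatnonzero(partner_mask)
    if len(w_idx) == 0 or len(p_idx) == 0:
        return []
    tree = cKDTree(structure.xyz[p_idx])
    contacts = []
    for wi in w_idx:
        for local in sorted(tree.query_ball_point(structure.xyz[wi], cutoff)):
            pj = p_idx[local]
            d = float(np.linalg.norm(structure.xyz[wi] - structure.xyz[pj]))
            if d <= cutoff:
                contacts.append(WaterContact(
                    water_id=structure.water_id(wi),
                    partner_residue=structure.residue_key(pj),
                    partner_atom=str(structure.atom_name[pj]),
                    distance_a=d,
                ))
    return contacts


def structural_waters(
    structure: Structure,
    min_contacts: int = MIN_CONTACTS,
    max_contacts: int | None = None,
    cutoff: float = HBOND_CUTOFF_A,
) -> set:
    """Waters making at least ``min_contacts`` distinct protein/ligand H-bonds.

    The definition targets waters with three or four hydrogen bonds; since
    a distance-only count can exceed four, the default reading is ">= 3".
    Pass ``max_contacts=4`` to apply the literal "three or four" cap.
    """
    counts: dict[tuple, set] = {}
    for c in water_contacts(structure, cutoff=cutoff):
        counts.setdefault(c.water_id, set()).add((c.partner_residue, c.partner_atom))
    out = set()
    for wid, partners in counts.items():
        n = len(partners)
        if n >= min_contacts and (max_contacts is None or n <= max_contacts):
            out.add(wid)
    return out


def pocket_filter(
    waters: set,
    structure: Structure,
    shell: float = POCKET_SHELL_A,
) -> set:
    """Retain waters whose oxygen lies within ``shell`` of any ligand atom.

    The boundary is closed (exactly ``shell`` is retained).
    """
    lig = np.flatnonzero(structure.ligand_mask)
    if len(lig) == 0:
        raise ValueError("no ligand atoms in structure")
    tree = cKDTree(structure.xyz[lig])
    kept = set()
    for wi in structure.water_oxygen_indices:
        wid = structure.water_id(wi)
        if wid in waters:
            d, _ = tree.query(structure.xyz[wi])
            if d <= shell:
                kept.add(wid)
    return kept


def retained_structural_waters(
    structure: Structure,
    min_contacts: int = MIN_CONTACTS,
    max_contacts: int | None = None,
    cutoff: float = HBOND_CUTOFF_A,
    shell: float = POCKET_SHELL_A,
) -> set:
    """Structural waters inside the ligand pocket shell."""
    sw = structural_waters(structure, min_contacts, max_contacts, cutoff)
    return pocket_filter(sw, structure, shell)


@dataclass
class WaterProbabilityMap:
    """Per-residue probability of H-bonding a retained structural water."""

    table: pd.DataFrame   # residue_key columns + numerator, denominator, probability
    denominator: int

    def probability(self, chain: str, resseq: int) -> float:
        sub = self.table[
            (self.table["chain"] == chain) & (self.table["resseq"] == resseq)
        ]
        return float(sub["probability"].iloc[0]) if len(sub) else 0.0


def hbond_probability(
    ensemble: Sequence[Structure],
    min_contacts: int = MIN_CONTACTS,
    max_contacts: int | None = None,
    cutoff: float = HBOND_CUTOFF_A,
    shell: float = POCKET_SHELL_A,
) -> WaterProbabilityMap:
    """Fraction of ensemble members in which each residue contacts a
    retained structural water.

    Probabilities are exact count ratios: numerator / ensemble size.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    counts: dict[tuple, int] = {}
    for s in ensemble:
        retained = retained_structural_waters(s, min_contacts, max_contacts, cutoff, shell)
        residues = {
            c.partner_residue
            for c in water_contacts(s, cutoff=cutoff)
            if c.water_id in retained
        }
        for rk in residues:
            counts[rk] = counts.get(rk, 0) + 1
    n = len(ensemble)
    rows = [
        {"chain": rk[0], "resseq": rk[1], "resname": rk[2],
         "numerator": num, "denominator": n, "probability": num / n}
        for rk, num in sorted(counts.items())
    ]
    return WaterProbabilityMap(
        table=pd.DataFrame(rows, columns=["chain", "resseq", "resname",
                                          "numerator", "denominator", "probability"]),
        denominator=n,
    )


def match_positions(
    xyz_a: np.ndarray,
    xyz_b: np.ndarray,
    tolerance: float = MATCH_TOLERANCE_A,
) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbour bipartite matching of two point sets.

    Candidate pairs within ``tolerance`` are accepted in order of
    increasing distance; each point is matched at most once.  Returns
    (index_a, index_b, distance) triples.
    """
    xyz_a = np.asarray(xyz_a, dtype=float).reshape(-1, 3)
    xyz_b = np.asarray(xyz_b, dtype=float).reshape(-1, 3)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return []
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=2)
    pairs = [
        (d[i, j], i, j)
        for i in range(len(xyz_a)) for j in range(len(xyz_b))
        if d[i, j] <= tolerance
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for dist, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            out.append((i, j, float(dist)))
    return out


def match_waters(
    ensemble_a: Sequence[Structure],
    ensemble_b: Sequence[Structure],
    tolerance: float = MATCH_TOLERANCE_A,
    structure_index: int = 0,
    **kwargs,
) -> list[tuple[tuple, tuple, float]]:
    """Match retained structural waters between two ensembles.

    Compares the retained waters of one representative structure from each
    ensemble (``structure_index``); returns (water_id_a, water_id_b,
    distance) triples from the greedy matcher.
    """
    sa = ensemble_a[structure_index]
    sb = ensemble_b[structure_index]
    ra = sorted(retained_structural_waters(sa, **kwargs))
    rb = sorted(retained_structural_waters(sb, **kwargs))

    def positions(s: Structure, wids):
        lookup = {s.water_id(i): s.xyz[i] for i in s.water_oxygen_indices}
        return np.array([lookup[w] for w in wids]).reshape(-1, 3)

    matches = match_positions(positions(sa, ra), positions(sb, rb), tolerance)
    return [(ra[i], rb[j], dist) for i, j, dist in matches]
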