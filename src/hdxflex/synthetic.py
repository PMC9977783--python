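"""Synthetic HDX-MS study generator.

Emits everything the downstream analysis consumes, with known ground truth:
a protein sequence, per-residue exchange classes per functional state,
a peptic peptide pool (cleavage after F/W/Y/L/I with missed cleavages),
noisy replicate centroid tables with undeuterated and fully-deuterated
controls, per-residue mutational-phenotype tables correlated with the
planted rigidity shifts, and toy structure ensembles with planted
coordinated waters in a ligand pocket.

The generative model mirrors the analysis assumptions: EX2 kinetics (each
exchangeable amide exchanges independently at its class rate, so the peptide
centroid drifts smoothly), a single per-peptide back-exchange retention
factor applied equally to all timepoints and to the fully-deuterated
control (which the FD correction therefore inverts exactly), and additive
Gaussian centroid noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .uptake import PeptideRecord, UNDEUTERATED, FULLY_DEUTERATED
from . import waters as _waters

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "EXCHANGE_CLASSES",
    "DEFAULT_TIMEPOINTS_S",
    "generate_ground_truth",
    "digest",
    "simulate_centroids",
    "true_uptake",
    "generate_phenotypes",
    "generate_toy_ensemble",
    "write_fasta",
    "read_fasta",
]

#: labeling timepoints in seconds: 0 s, 30 s, 45 s, 1 min, 5 min, 25 min,
#: 1 h, 2 h, 4 h — a grid spanning five decades of exchange rates
DEFAULT_TIMEPOINTS_S = (0.0, 30.0, 45.0, 60.0, 300.0, 1500.0, 3600.0, 7200.0, 14400.0)

#: exchange classes in decreasing rigidity (non never exchanges)
EXCHANGE_CLASSES = ("non", "slow", "medium", "fast")

#: default class rates (1/s); separable on the 30 s – 4 h grid
DEFAULT_RATES = {"fast": 0.1, "medium": 1e-2, "slow": 1e-4, "non": 0.0}

# average residue masses (Da) for plausible peptide centroid baselines
_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
_WATER_MASS = 18.02


@dataclass
class SynthConfig:
    """Study design for the synthetic generator.

    Defaults reproduce the emulated experiment: nine labeling timepoints,
    back-exchange retention 0.70 +/- 0.157 (truncated normal on (0, 1]),
    pepsin-like cleavage after F/W/Y/L/I with missed cleavages, peptide
    lengths 4-40, and a configurable fraction of residues whose exchange
    class differs between the two designated states.
    """

    seed: int = 0
    timepoints_s: tuple = DEFAULT_TIMEPOINTS_S
    n_replicates: int = 3
    noise_sd: float = 0.05          # deuterons, additive on centroids
    backexchange_mean: float = 0.70
    backexchange_sd: float = 0.157
    cleavage_residues: frozenset = frozenset("FWYLI")
    max_missed_cleavages: int = 2
    min_peptide_length: int = 4
    max_peptide_length: int = 40
    frac_shifted_residues: float = 0.2
    shift_block_length: int = 7     # planted shifts come in contiguous runs
    sequence: str | None = None     # supply a sequence, or generate one
    sequence_length: int = 120
    states: tuple = ("IPTG", "DNA")
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    # experimental samples are labeled in diluted buffer, so their plateau
    # can sit below the fully-deuterated control's; 1.0 = same saturation
    labeling_saturation: float = 1.0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints_s)
        if tp[0] != 0.0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must start at 0 and strictly increase")
        self.timepoints_s = tp
        if not (0.0 < self.backexchange_mean <= 1.0):
            raise ValueError("backexchange_mean must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.frac_shifted_residues <= 1.0):
            raise ValueError("frac_shifted_residues must be in [0, 1]")
        if not (self.rates["fast"] > self.rates["medium"] > self.rates["slow"] > 0):
            raise ValueError("rates must satisfy fast > medium > slow > 0")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["cleavage_residues"] = sorted(self.cleavage_residues)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["cleavage_residues"] = frozenset(d["cleavage_residues"])
        d["timepoints_s"] = tuple(d["timepoints_s"])
        d["states"] = tuple(d["states"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known per-residue exchange behaviour for each functional state."""

    sequence: str
    states: tuple
    #: (state, 1-based residue) -> exchange class; only eligible residues
    #: (position >= 3, non-proline) carry a class
    per_state_residue_class: dict
    rates: Mapping[str, float]

    def eligible_residues(self) -> list[int]:
        return [
            i for i in range(3, len(self.sequence) + 1)
            if self.sequence[i - 1] != "P"
        ]

    def shifted_residues(self) -> dict[int, str]:
        """Residues whose class differs between the two designated states.

        Maps residue -> state in which it is MORE rigid (slower class).
        """
        s1, s2 = self.states[0], self.states[1]
        order = {c: i for i, c in enumerate(EXCHANGE_CLASSES)}  # non most rigid
        out = {}
        for r in self.eligible_residues():
            c1 = self.per_state_residue_class[(s1, r)]
            c2 = self.per_state_residue_class[(s2, r)]
            if c1 != c2:
                out[r] = s1 if order[c1] < order[c2] else s2
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "residue": r, "exchange_class": c}
            for (s, r), c in sorted(self.per_state_residue_class.items())
        ]
        return pd.DataFrame(rows)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    # down-weight proline so most positions are exchange-eligible
    w = np.array([1.0] * 20)
    w[aas.index("P")] = 0.3
    w /= w.sum()
    return "".join(rng.choice(aas, size=length, p=w))


def generate_ground_truth(config: SynthConfig) -> GroundTruth:
    """Draw a protein and per-state residue exchange classes.

    Exactly ``round(frac_shifted_residues * n_eligible)`` eligible residues
    differ in class between the two designated states.  Shifts are planted
    in contiguous blocks (rigidity differences in real proteins involve
    whole secondary-structure elements, and contiguity is what makes them
    visible through peptide-level averaging); each block is more rigid in
    one state, with the direction alternating between blocks.
    """
    rng = np.random.default_rng(config.seed)
    seq = (config.sequence or _random_sequence(rng, config.sequence_length)).upper()
    if len(seq) < 10:
        raise ValueError("sequence must have at least 10 residues")

    eligible = [i for i in range(3, len(seq) + 1) if seq[i - 1] != "P"]
    n_shift = int(round(config.frac_shifted_residues * len(eligible)))

    s1, s2 = config.states[0], config.states[1]
    classes = {}
    base_probs = np.array([0.15, 0.25, 0.30, 0.30])  # non, slow, medium, fast
    for r in eligible:
        c = rng.choice(EXCHANGE_CLASSES, p=base_probs)
        for s in config.states:
            classes[(s, r)] = c

    # plant contiguous shifted blocks over the eligible residues until the
    # exact count is reached
    remaining = n_shift
    free = list(eligible)
    toggle = True
    while remaining > 0 and free:
        blk = min(config.shift_block_length, remaining)
        # pick a start with room for a run of `blk` consecutive free residues
        anchor = int(rng.integers(0, len(free)))
        run = free[anchor:anchor + blk]
        rigid_state, flex_state = (s1, s2) if toggle else (s2, s1)
        rigid_class = str(rng.choice(["non", "slow"]))
        flex_class = str(rng.choice(["medium", "fast"]))
        for r in run:
            classes[(rigid_state, r)] = rigid_class
            classes[(flex_state, r)] = flex_class
        free = [r for r in free if r not in set(run)]
        remaining -= len(run)
        toggle = not toggle

    return GroundTruth(
        sequence=seq,
        states=tuple(config.states),
        per_state_residue_class=classes,
        rates=dict(config.rates),
    )


def digest(sequence: str, config: SynthConfig) -> list[PeptideRecord]:
    """Enumerate peptic peptides with missed cleavages.

    Cut sites fall after each residue in the cleavage set; peptides span up
    to ``max_missed_cleavages`` internal sites, giving the overlapping pool
    characteristic of pepsin digestion.  Length bounds are applied after
    enumeration.  A sequence with no cut sites yields the single full-length
    peptide (if within bounds).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    cuts = [0] + [i + 1 for i, aa in enumerate(seq) if aa in config.cleavage_residues]
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + config.max_missed_cleavages, len(cuts))):
            start, end = cuts[i] + 1, cuts[j]
            length = end - start + 1
            if config.min_peptide_length <= length <= config.max_peptide_length:
                peptides.append(PeptideRecord.from_sequence(seq[start - 1:end], start))
    return peptides


def _exchangeable_positions(peptide: PeptideRecord) -> list[int]:
    """Parent-protein positions of the peptide's exchangeable amides."""
    return [
        peptide.start + k
        for k in range(2, len(peptide.sequence))
        if peptide.sequence[k] != "P"
    ]


def true_uptake(
    truth: GroundTruth,
    peptide: PeptideRecord,
    state: str,
    timepoints_s: Sequence[float],
) -> np.ndarray:
    """Noise-free deuteron uptake of a peptide under the ground truth.

    Each exchangeable amide contributes ``1 - exp(-k * t)`` at its class
    rate; non-exchanging residues contribute zero.
    """
    t = np.asarray(timepoints_s, dtype=float)
    d = np.zeros_like(t)
    for pos in _exchangeable_positions(peptide):
        k = truth.rates[truth.per_state_residue_class[(state, pos)]]
        if k > 0:
            d += -np.expm1(-k * t)
    return d


def simulate_centroids(
    truth: GroundTruth,
    peptides: Sequence[PeptideRecord],
    config: SynthConfig,
) -> pd.DataFrame:
    """Emit a replicate centroid table with controls for every peptide.

    Per peptide, a back-exchange retention factor ``b`` is drawn once from
    a truncated normal on (0, 1] and applied to every timepoint and to the
    fully-deuterated control, so the downstream FD correction inverts it
    exactly.  Experimental rows are
    ``m_t = m_0 + b * saturation * D_true(t) + Normal(0, noise_sd)``;
    control rows are noise-free (``m_0`` and ``m_0 + b * max_protons``).
    Peptides with an empty exchangeable budget are skipped.
    """
    rng = np.random.default_rng(config.seed + 1)
    a = (0.0 - config.backexchange_mean) / config.backexchange_sd
    b_hi = (1.0 - config.backexchange_mean) / config.backexchange_sd

    rows = []
    for pep in peptides:
        if pep.end > len(truth.sequence) or pep.start < 1:
            raise ValueError(
                f"peptide {pep.peptide_id} interval outside sequence of "
                f"length {len(truth.sequence)}"
            )
        if pep.max_protons < 1:
            continue
        m0 = sum(_RESIDUE_MASS[aa] for aa in pep.sequence) + _WATER_MASS
        b = float(truncnorm.rvs(
            a, b_hi, loc=config.backexchange_mean, scale=config.backexchange_sd,
            random_state=rng,
        ))
        b = min(max(b, 1e-6), 1.0)

        common = dict(
            peptide_id=pep.peptide_id, sequence=pep.sequence,
            start=pep.start, end=pep.end,
        )
        rows.append({**common, "state": UNDEUTERATED, "timepoint_s": 0.0,
                     "replicate": 1, "centroid_mass_da": m0})
        rows.append({**common, "state": FULLY_DEUTERATED, "timepoint_s": 0.0,
                     "replicate": 1, "centroid_mass_da": m0 + b * pep.max_protons})
        for state in truth.states:
            d_true = true_uptake(truth, pep, state, config.timepoints_s)
            for ti, t in enumerate(config.timepoints_s):
                for rep in range(1, config.n_replicates + 1):
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                    m_t = m0 + b * config.labeling_saturation * d_true[ti] + eps
                    rows.append({**common, "state": state, "timepoint_s": t,
                                 "replicate": rep, "centroid_mass_da": m_t})
    return pd.DataFrame(rows)


def generate_phenotypes(
    truth: GroundTruth,
    p_concordant: float,
    seed: int,
    directions: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Assign mutational-phenotype classes correlated with planted rigidity.

    Residues more rigid in the first designated state receive class ``I_S``
    (constitutive repression) with probability ``p_concordant``; residues
    more rigid in the second state receive ``I_minus`` (constitutive
    expression) analogously.  All remaining residues are class ``other``
    with a random mutation-tolerance flag.

    ``directions`` (residue -> state in which it is more rigid) defaults to
    the truth's shifted-residue map; callers analysing region-level labels
    may pass the region map instead.
    """
    if not (0.0 <= p_concordant <= 1.0):
        raise ValueError("p_concordant must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if directions is None:
        directions = truth.shifted_residues()
    s1 = truth.states[0]
    rows = []
    for r in range(1, len(truth.sequence) + 1):
        direction = directions.get(r)
        if direction is not None and rng.random() < p_concordant:
            cls = "I_S" if direction == s1 else "I_minus"
            tolerant = False
        else:
            cls = "other"
            tolerant = bool(rng.random() < 0.5)
        rows.append({"residue": r, "class": cls, "tolerant": tolerant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy structure ensembles with planted coordinated waters


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ], axis=1)


def generate_toy_ensemble(
    n_structures: int,
    n_planted_waters: int,
    seed: int,
    n_decoy_waters: int = 2,
    jitter_amplitude: float = 0.15,
    contact_distance: float = 2.8,
) -> list["_waters.Structure"]:
    """Build a toy ensemble with planted structural waters in a ligand pocket.

    Each planted water oxygen sits ~4.5 A from a three-atom ligand and is
    given three protein N/O partner atoms at ``contact_distance``, so it
    satisfies the structural-water definition (>= 3 heavy-atom hydrogen
    bonds within 3.2 A) inside the 6 A pocket shell.  Decoy waters
    alternate between two failure modes: in-pocket with only two partners,
    and fully coordinated but outside the shell.  All atoms are jittered
    per structure inside a ball of radius ``jitter_amplitude`` (< 0.25 A),
    so the same water stays within 0.5 A of itself across structures.
    """
    if n_structures < 1:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(seed)

    atoms = []  # (name, element, resname, resseq, chain, xyz, het)

    def add(name, element, resname, resseq, chain, xyz, het):
        atoms.append((name, element, resname, resseq, chain,
                      np.asarray(xyz, dtype=float), het))

    # ligand at the origin
    add("C1", "C", "LIG", 1, "X", (0.0, 0.0, 0.0), True)
    add("O1", "O", "LIG", 1, "X", (1.3, 0.0, 0.0), True)
    add("N1", "N", "LIG", 1, "X", (-1.3, 0.0, 0.0), True)

    resseq = 1
    n_sites = max(n_planted_waters + n_decoy_waters, 1)
    # pocket sites on a staggered ring 5.2 A from the ligand axis: inside
    # the 6 A shell, > 4 A from every ligand atom (no accidental ligand
    # contact even after jitter), and pairwise > 6.5 A apart so no water
    # can reach another site's partner atoms
    if n_sites > 6:
        raise ValueError("toy geometry supports at most 6 water sites")
    angles = 2 * np.pi * np.arange(n_sites) / max(n_sites, 1)
    site_pos = np.stack([
        5.2 * np.cos(angles),
        5.2 * np.sin(angles),
        np.where(np.arange(n_sites) % 2 == 0, 2.2, -2.2),
    ], axis=1)
    far_dirs = _fibonacci_directions(max(n_sites, 4))

    partner_dirs = _fibonacci_directions(3)

    def add_site(center: np.ndarray, n_partners: int):
        nonlocal resseq
        resseq += 1
        add("O", "O", "HOH", resseq, "W", center, True)
        names = ["N", "O", "OG"]
        elements = ["N", "O", "O"]
        resseq += 1
        for k in range(n_partners):
            add(names[k], elements[k], "SER", resseq, "A",
                center + contact_distance * partner_dirs[k], False)

    for i in range(n_planted_waters):
        add_site(site_pos[i], 3)                  # in pocket, 3 partners
    for j in range(n_decoy_waters):
        if j % 2 == 0:                            # in pocket, too few partners
            add_site(site_pos[n_planted_waters + j], 2)
        else:                                     # coordinated but outside shell
            add_site(15.0 * far_dirs[j], 3)

    base_xyz = np.stack([a[5] for a in atoms])
    structures = []
    for _ in range(n_structures):
        # isotropic jitter inside a ball of radius jitter_amplitude
        u = rng.normal(size=base_xyz.shape)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = jitter_amplitude * rng.random(len(atoms)) ** (1 / 3)
        xyz = base_xyz + u * radii[:, None]
        structures.append(_waters.Structure(
            xyz=xyz,
            element=np.array([a[1] for a in atoms]),
            atom_name=np.array([a[0] for a in atoms]),
            resname=np.array([a[2] for a in atoms]),
            resseq=np.array([a[3] for a in atoms], dtype=int),
            chain=np.array([a[4] for a in atoms]),
            het=np.array([a[6] for a in atoms], dtype=bool),
        ))
    return structures


# ---------------------------------------------------------------------------
# sequence I/O


def write_fasta(sequence: str, path, name: str = "synthetic_protein") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(str(path), "fasta")).seq)
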