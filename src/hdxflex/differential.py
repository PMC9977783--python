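"""Differential exchange between functional states and residue rigidity labels.

For a peptide measured in two states, the fractional difference at each
common timepoint is

    dHX(t) = (D1(t) - D2(t)) / max_protons

with uncertainty propagated from the replicate SDs of the two means.
A residue is labeled "more rigid" in one state when a covering peptide
shows a fractional difference larger than a threshold (default 20% of the
amide budget) in that direction at a minimum number of timepoints (default
three).  Residues covered by qualifying peptides in both directions are
labeled ambiguous; covered residues with no qualifying peptide are "none";
uncovered residues carry "no_data".  Raising the threshold or the minimum
timepoint count can only shrink the labeled sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .uptake import PeptideRecord, UptakeCurve, FULLY_DEUTERATED

__all__ = [
    "FractionalDifference",
    "ResidueLabel",
    "ResidueFlexMap",
    "LABELS",
    "curate_peptides",
    "fractional_difference",
    "classify_residues",
    "write_flexmap_csv",
    "write_flexmap_bed",
]

DEFAULT_THRESHOLD = 0.20
DEFAULT_MIN_TIMEPOINTS = 3

LABELS = ("more_rigid_in_state1", "more_rigid_in_state2", "none", "ambiguous", "no_data")


def curate_peptides(
    centroids: pd.DataFrame,
    required_states: Iterable[str],
    require_fd: bool = True,
    min_replicates: int = 2,
) -> set:
    """Peptides with replicate coverage in every required state.

    A peptide passes when it has at least ``min_replicates`` replicates at
    every timepoint observed for it in *every* required state, and (if
    ``require_fd``) a fully-deuterated control row.  Deterministic.
    """
    required = list(required_states)
    if not required:
        raise ValueError("required_states is empty")
    passed = set()
    for pid, grp in centroids.groupby("peptide_id"):
        if require_fd and not (grp["state"] == FULLY_DEUTERATED).any():
            continue
        ok = True
        for state in required:
            sub = grp[grp["state"] == state]
            if sub.empty:
                ok = False
                break
            reps = sub.groupby("timepoint_s")["replicate"].nunique()
            if (reps < min_replicates).any():
                ok = False
                break
        if ok:
            passed.add(pid)
    return passed


@dataclass
class FractionalDifference:
    """Per-timepoint fractional exchange difference for one peptide."""

    peptide_id: str
    state1: str
    state2: str
    timepoints_s: np.ndarray
    delta_hx: np.ndarray        # (D1 - D2) / max_protons; >0 means state2 more protected
    uncertainty: np.ndarray     # SE-propagated, same units

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "peptide_id": self.peptide_id,
            "state1": self.state1,
            "state2": self.state2,
            "timepoint_s": self.timepoints_s,
            "delta_hx": self.delta_hx,
            "uncertainty": self.uncertainty,
        })


def fractional_difference(
    curve1: UptakeCurve,
    curve2: UptakeCurve,
    peptide: PeptideRecord,
) -> FractionalDifference:
    """Fractional exchange difference on the common timepoint grid.

    ``delta_hx(t) = (D1(t) - D2(t)) / max_protons``; the uncertainty is the
    standard error of the difference of independent replicate means,
    ``sqrt(sd1^2/n1 + sd2^2/n2) / max_protons``.
    """
    if curve1.peptide_id != curve2.peptide_id:
        raise ValueError("curves belong to different peptides")
    common = np.intersect1d(curve1.timepoints_s, curve2.timepoints_s)
    if len(common) == 0:
        raise ValueError("no common timepoints between states")
    i1 = np.searchsorted(curve1.timepoints_s, common)
    i2 = np.searchsorted(curve2.timepoints_s, common)
    mp = peptide.max_protons
    delta = (curve1.mean_d[i1] - curve2.mean_d[i2]) / mp
    unc = np.sqrt(
        curve1.sd_d[i1] ** 2 / curve1.n_replicates[i1]
        + curve2.sd_d[i2] ** 2 / curve2.n_replicates[i2]
    ) / mp
    return FractionalDifference(
        peptide_id=peptide.peptide_id,
        state1=curve1.state,
        state2=curve2.state,
        timepoints_s=common,
        delta_hx=delta,
        uncertainty=unc,
    )


@dataclass
class ResidueLabel:
    label: str
    peptides: tuple = ()
    n_qualifying_timepoints: int = 0


@dataclass
class ResidueFlexMap:
    """Residue-level rigidity classification for one state pair."""

    state1: str
    state2: str
    labels: dict            # residue (1-based) -> ResidueLabel
    threshold: float
    min_timepoints: int

    def residues_with(self, label: str) -> list[int]:
        return sorted(r for r, rl in self.labels.items() if rl.label == label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue": r, "label": rl.label,
             "n_qualifying_timepoints": rl.n_qualifying_timepoints,
             "peptides": ";".join(rl.peptides)}
            for r, rl in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["residue", "label",
                                           "n_qualifying_timepoints", "peptides"])


def classify_residues(
    diffs: Sequence[FractionalDifference],
    peptides: Sequence[PeptideRecord],
    threshold: float = DEFAULT_THRESHOLD,
    min_timepoints: int = DEFAULT_MIN_TIMEPOINTS,
    n_residues: int | None = None,
) -> ResidueFlexMap:
    """Label residues differentially rigid from peptide-level differences.

    A peptide *qualifies* for a state when the fractional difference favors
    that state (less exchange there) by more than ``threshold`` at
    ``min_timepoints`` or more timepoints.  Every residue covered by a
    qualifying peptide inherits its direction; opposing qualifying peptides
    make a residue ambiguous.  ``n_residues`` extends the map with
    ``no_data`` rows for an uncovered tail (defaults to the largest covered
    position).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    by_id: Mapping[str, PeptideRecord] = {p.peptide_id: p for p in peptides}
    state1 = diffs[0].state1 if diffs else "state1"
    state2 = diffs[0].state2 if diffs else "state2"

    # per-residue tallies of qualifying peptides in each direction
    support: dict[int, dict[str, list]] = {}
    covered: set[int] = set()
    for d in diffs:
        pep = by_id.get(d.peptide_id)
        if pep is None:
            raise ValueError(f"no PeptideRecord for {d.peptide_id}")
        covered.update(range(pep.start, pep.end + 1))
        # delta > threshold: state1 exchanged more -> state2 more rigid.
        # The comparison is strict; the epsilon keeps round-off from the
        # affine centroid arithmetic from tipping a value sitting exactly
        # on the boundary (e.g. a one-residue shift in a 5-amide peptide).
        eps = 1e-9
        n_s2 = int(np.sum(d.delta_hx > threshold + eps))
        n_s1 = int(np.sum(d.delta_hx < -threshold - eps))
        for direction, n in (("state2", n_s2), ("state1", n_s1)):
            if n >= min_timepoints:
                for r in range(pep.start, pep.end + 1):
                    support.setdefault(r, {"state1": [], "state2": []})
                    support[r][direction].append((d.peptide_id, n))

    max_res = n_residues or (max(covered) if covered else 0)
    labels: dict[int, ResidueLabel] = {}
    for r in range(1, max_res + 1):
        if r not in covered:
            labels[r] = ResidueLabel("no_data")
            continue
        s = support.get(r)
        if s is None or (not s["state1"] and not s["state2"]):
            labels[r] = ResidueLabel("none")
            continue
        if s["state1"] and s["state2"]:
            peps = tuple(sorted({p for p, _ in s["state1"] + s["state2"]}))
            labels[r] = ResidueLabel("ambiguous", peps, 0)
            continue
        direction = "state1" if s["state1"] else "state2"
        entries = s[direction]
        labels[r] = ResidueLabel(
            f"more_rigid_in_{direction}",
            tuple(sorted({p for p, _ in entries})),
            max(n for _, n in entries),
        )
    return ResidueFlexMap(state1, state2, labels, threshold, min_timepoints)


def write_flexmap_csv(flexmap: ResidueFlexMap, path) -> None:
    flexmap.to_frame().to_csv(path, index=False)


def write_flexmap_bed(flexmap: ResidueFlexMap, path, chrom: str = "protein") -> None:
    """Labeled segments as BED (0-based half-open) for track-style viewers."""
    df = flexmap.to_frame()
    with open(path, "w") as fh:
        run_label, run_start, prev = None, None, None
        for _, row in df.iterrows():
            r, lab = int(row["residue"]), row["label"]
            if lab != run_label or (prev is not None and r != prev + 1):
                if run_label not in (None, "no_data"):
                    fh.write(f"{chrom}\t{run_start - 1}\t{prev}\t{run_label}\n")
                run_label, run_start = lab, r
            prev = r
        if run_label not in (None, "no_data") and prev is not None:
            fh.write(f"{chrom}\t{run_start - 1}\t{prev}\t{run_label}\n")
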