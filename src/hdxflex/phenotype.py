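"""Cross-tabulation of rigidity labels against mutational phenotype classes.

Point-mutant screens bin residue positions by the phenotype their mutation
causes: constitutive repression (``I_S``, unresponsive to inducer),
constitutive expression (``I_minus``), or neither (``other``, optionally
flagged mutation-tolerant).  For each differentially rigid residue group
this module reports the percentage of members in each phenotype class --
the expectation being that positions rigidified in the inducer-bound state
enrich for I_S and positions rigidified in the DNA-bound state enrich for
I_minus.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .differential import ResidueFlexMap

__all__ = ["PHENOTYPE_CLASSES", "GroupEnrichment", "EnrichmentTable", "enrichment"]

PHENOTYPE_CLASSES = ("I_S", "I_minus", "other")


@dataclass
class GroupEnrichment:
    """Phenotype composition of one rigidity group."""

    group: str
    n_residues: int                  # denominator (with phenotype data)
    n_missing_phenotype: int
    pct_I_S: float | None
    pct_I_minus: float | None
    pct_other: float | None
    pct_tolerant_among_other: float | None
    counts: dict


@dataclass
class EnrichmentTable:
    state1: str
    state2: str
    groups: dict                      # group name -> GroupEnrichment

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            rows.append({
                "group": g.group, "n_residues": g.n_residues,
                "n_missing_phenotype": g.n_missing_phenotype,
                "pct_I_S": g.pct_I_S, "pct_I_minus": g.pct_I_minus,
                "pct_other": g.pct_other,
                "pct_tolerant_among_other": g.pct_tolerant_among_other,
            })
        return pd.DataFrame(rows)

    def format_text(self) -> str:
        lines = [f"phenotype enrichment ({self.state1} vs {self.state2})"]
        for g in self.groups.values():
            if g.n_residues == 0:
                lines.append(f"  {g.group}: no residues")
                continue
            lines.append(
                f"  {g.group} (n={g.n_residues}): "
                f"I_S {g.pct_I_S:.0f}%, I_minus {g.pct_I_minus:.0f}%, "
                f"other {g.pct_other:.0f}% "
                f"(tolerant among other: "
                + (f"{g.pct_tolerant_among_other:.0f}%" if g.pct_tolerant_among_other is not None else "n/a")
                + ")"
            )
        return "\n".join(lines)


def enrichment(
    flexmap: ResidueFlexMap,
    phenotypes: pd.DataFrame,
    region_filter: tuple[int, int] | None = None,
) -> EnrichmentTable:
    """Phenotype-class percentages within each rigidity group.

    ``phenotypes`` has columns residue, class, tolerant.  Ambiguous and
    no-data residues never enter a group; residues without a phenotype
    entry are excluded from the denominator and counted separately.
    ``region_filter`` (1-based inclusive) restricts the tabulation, e.g.
    to a core domain.
    """
    if phenotypes["residue"].duplicated().any():
        raise ValueError("duplicate residues in phenotype table")
    bad = set(phenotypes["class"]) - set(PHENOTYPE_CLASSES)
    if bad:
        raise ValueError(f"unknown phenotype classes: {sorted(bad)}")
    pheno = phenotypes.set_index("residue")

    groups = {}
    for group in ("more_rigid_in_state1", "more_rigid_in_state2"):
        members = flexmap.residues_with(group)
        if region_filter is not None:
            lo, hi = region_filter
            members = [r for r in members if lo <= r <= hi]
        with_ph = [r for r in members if r in pheno.index]
        n_missing = len(members) - len(with_ph)
        counts = {c: 0 for c in PHENOTYPE_CLASSES}
        n_tolerant_other = 0
        for r in with_ph:
            cls = pheno.loc[r, "class"]
            counts[cls] += 1
            if cls == "other" and bool(pheno.loc[r, "tolerant"]):
                n_tolerant_other += 1
        n = len(with_ph)
        if n == 0:
            ge = GroupEnrichment(group, 0, n_missing, None, None, None, None, counts)
        else:
            ge = GroupEnrichment(
                group=group, n_residues=n, n_missing_phenotype=n_missing,
                pct_I_S=100.0 * counts["I_S"] / n,
                pct_I_minus=100.0 * counts["I_minus"] / n,
                pct_other=100.0 * counts["other"] / n,
                pct_tolerant_among_other=(
                    100.0 * n_tolerant_other / counts["other"]
                    if counts["other"] else None
                ),
                counts=counts,
            )
        groups[group] = ge
    return EnrichmentTable(flexmap.state1, flexmap.state2, groups)
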