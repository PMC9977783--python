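"""Per-peptide deuterium uptake: back-exchange correction and kinetic fitting.

The measured quantity in an HDX-MS experiment is the intensity-weighted
centroid mass of a peptide's isotope envelope.  Deuteration at labeling time
``t`` is recovered from three centroids -- undeuterated (``m_0``), timepoint
(``m_t``) and fully deuterated (``m_inf``) -- by the back-exchange-corrected
ratio

    D(t) = max_protons * (m_t - m_0) / (m_inf - m_0)

where ``max_protons`` is the theoretical number of exchangeable backbone
amides (peptide length minus the two N-terminal residues, minus prolines
beyond them).  Uptake curves D(t) are then summarised by a constrained
triple-exponential model partitioning the amide budget into fast-, medium-
and slow-exchanging and non-exchanging protons,

    D(t) = A*(1 - exp(-k1 t)) + B*(1 - exp(-k2 t)) + C*(1 - exp(-k3 t))

with A + B + C + NE = max_protons and k1 > k2 > k3 > 0, so that D(0) = 0 and
D(inf) = max_protons - NE.  Peptides that barely exchange over the
experiment (< 0.5 D at the final timepoint) are fit with the fast term
removed (A = 0), since k1 is then unidentifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "STANDARD_RESIDUES",
    "PeptideRecord",
    "UptakeCurve",
    "ExchangeFit",
    "BackExchangeSummary",
    "compute_max_protons",
    "count_exchange_prolines",
    "deuteration",
    "build_uptake_curve",
    "fit_uptake",
    "predict_uptake",
    "backexchange_summary",
    "fit_all_peptides",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: state labels reserved for control rows in centroid tables
UNDEUTERATED = "UNDEUTERATED"
FULLY_DEUTERATED = "FULLY_DEUTERATED"

#: deuteration outside [0, max_protons] by more than this is flagged
OVER_RANGE_TOLERANCE_D = 0.5


def count_exchange_prolines(sequence: str) -> int:
    """Prolines at peptide positions >= 3 (1-based).

    The two N-terminal residues are excluded from the exchangeable budget
    regardless of identity, so prolines there are not double-counted.
    """
    return sequence[2:].count("P")


def compute_max_protons(sequence: str) -> int:
    """Theoretical maximum number of exchangeable backbone amide protons.

    ``len - 2 - (prolines at positions >= 3)``: the first two residues
    back-exchange too quickly to retain label, and proline has no amide
    hydrogen.  Never negative.

    Raises
    ------
    ValueError
        If the sequence contains a non-standard residue or is shorter
        than 2 residues.
    """
    seq = sequence.upper()
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in {sequence!r}")
    if len(seq) < 2:
        raise ValueError("peptide must have at least 2 residues")
    return max(0, len(seq) - 2 - count_exchange_prolines(seq))


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide located in its parent protein.

    ``start``/``end`` are 1-based inclusive positions; ``max_protons`` is
    the exchangeable-amide budget used throughout the analysis.
    """

    peptide_id: str
    sequence: str
    start: int
    end: int
    max_protons: int
    num_prolines: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"interval [{self.start},{self.end}] inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        expected = max(0, len(self.sequence) - 2 - self.num_prolines)
        if self.max_protons != expected:
            raise ValueError(
                f"max_protons={self.max_protons} != len-2-prolines={expected}"
            )

    @classmethod
    def from_sequence(cls, sequence: str, start: int, peptide_id: str | None = None) -> "PeptideRecord":
        seq = sequence.upper()
        end = start + len(seq) - 1
        return cls(
            peptide_id=peptide_id or f"{start}-{end}",
            sequence=seq,
            start=start,
            end=end,
            max_protons=compute_max_protons(seq),
            num_prolines=count_exchange_prolines(seq),
        )


def deuteration(m_0: float, m_t: float, m_inf: float, max_protons: int) -> float:
    """Back-exchange-corrected deuteration in deuterons.

    Values may slightly exceed [0, max_protons] under centroid noise and are
    deliberately not clamped (clamping would bias downstream fits); callers
    flag excursions beyond ``OVER_RANGE_TOLERANCE_D``.
    """
    if m_inf <= m_0:
        raise ValueError(
            f"degenerate controls: fully-deuterated centroid {m_inf} <= "
            f"undeuterated centroid {m_0}"
        )
    if max_protons <= 0:
        raise ValueError("max_protons must be positive")
    return max_protons * (m_t - m_0) / (m_inf - m_0)


@dataclass
class UptakeCurve:
    """Replicate-averaged deuteration vs. labeling time for one peptide/state."""

    peptide_id: str
    state: str
    timepoints_s: np.ndarray        # strictly increasing, seconds
    mean_d: np.ndarray              # deuterons
    sd_d: np.ndarray                # deuterons, propagated from centroid SD
    n_replicates: np.ndarray        # per timepoint
    max_protons: int
    over_range: bool = False        # any mean outside [0, max] by > 0.5 D

    def __post_init__(self) -> None:
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        self.mean_d = np.asarray(self.mean_d, dtype=float)
        self.sd_d = np.asarray(self.sd_d, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)


def build_uptake_curve(
    centroids: pd.DataFrame,
    peptide: PeptideRecord,
    state: str,
) -> UptakeCurve:
    """Compute an uptake curve from a centroid table for one peptide/state.

    Replicate centroids are averaged per timepoint first, then the
    back-exchange correction is applied to the mean (the correction is
    affine in ``m_t``, so the order does not bias the mean); the per-timepoint
    SD of replicate centroids is propagated through the same linear map.

    ``centroids`` uses the long schema: columns peptide_id, state,
    timepoint_s, replicate, centroid_mass_da; control rows carry state
    ``UNDEUTERATED`` / ``FULLY_DEUTERATED``.
    """
    rows = centroids[centroids["peptide_id"] == peptide.peptide_id]
    m0_rows = rows[rows["state"] == UNDEUTERATED]
    minf_rows = rows[rows["state"] == FULLY_DEUTERATED]
    if m0_rows.empty or minf_rows.empty:
        raise ValueError(
            f"peptide {peptide.peptide_id}: missing undeuterated and/or "
            "fully-deuterated control rows; cannot back-exchange-correct"
        )
    m0 = float(m0_rows["centroid_mass_da"].mean())
    minf = float(minf_rows["centroid_mass_da"].mean())

    exp = rows[rows["state"] == state]
    if exp.empty:
        raise ValueError(f"peptide {peptide.peptide_id}: no rows for state {state!r}")

    grouped = exp.groupby("timepoint_s")["centroid_mass_da"]
    t = np.array(sorted(grouped.groups.keys()), dtype=float)
    mean_c = grouped.mean().reindex(t).to_numpy()
    sd_c = grouped.std(ddof=1).reindex(t).fillna(0.0).to_numpy()
    n = grouped.count().reindex(t).to_numpy()

    scale = peptide.max_protons / (minf - m0)
    mean_d = np.array([deuteration(m0, m, minf, peptide.max_protons) for m in mean_c])
    sd_d = sd_c * scale

    over = bool(
        np.any(mean_d < -OVER_RANGE_TOLERANCE_D)
        or np.any(mean_d > peptide.max_protons + OVER_RANGE_TOLERANCE_D)
    )
    return UptakeCurve(
        peptide_id=peptide.peptide_id,
        state=state,
        timepoints_s=t,
        mean_d=mean_d,
        sd_d=sd_d,
        n_replicates=n,
        max_protons=peptide.max_protons,
        over_range=over,
    )


@dataclass
class ExchangeFit:
    """Constrained triple-exponential fit of an uptake curve.

    Amplitudes partition the amide budget (A + B + C + NE = max_protons,
    all >= 0); rates are strictly ordered k1 > k2 > k3 > 0.  When
    ``modified_slow_fit`` is set the fast term was removed (A = 0, k1 NaN).
    """

    peptide_id: str
    state: str
    A: float
    B: float
    C: float
    NE: float
    k1: float       # 1/s; NaN when modified_slow_fit
    k2: float
    k3: float
    rss: float      # squared deuterons
    modified_slow_fit: bool
    fit_ok: bool
    max_protons: int

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return predict_uptake(t, self.A, self.B, self.C, self.k1, self.k2, self.k3)


def predict_uptake(t, A, B, C, k1, k2, k3):
    """Model uptake: sum of saturating exponentials, zero at t = 0."""
    t = np.asarray(t, dtype=float)
    out = B * -np.expm1(-k2 * t) + C * -np.expm1(-k3 * t)
    if A > 0 and np.isfinite(k1):
        out = out + A * -np.expm1(-k1 * t)
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(phi: np.ndarray) -> np.ndarray:
    z = np.concatenate([phi, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# fitter internals: rates are reparameterized as k1 = exp(th1),
# k2 = k1*sigmoid(th2), k3 = k2*sigmoid(th3) so the strict ordering holds at
# every iterate; amplitudes as max_protons * softmax(phi1..phi3, 0) so the
# budget constraint and non-negativity hold by construction.

_DEFAULT_GRID_POINTS = 5  # log-spaced multi-start lattice over 1e-5..1 /s


def _unpack_full(theta: np.ndarray, max_protons: float):
    th1, th2, th3, p1, p2, p3 = theta
    k1 = math.exp(min(max(th1, -25.0), 25.0))
    k2 = k1 * float(_sigmoid(np.array(th2)))
    k3 = k2 * float(_sigmoid(np.array(th3)))
    w = _softmax(np.array([p1, p2, p3]))
    A, B, C, NE = max_protons * w
    return A, B, C, NE, k1, k2, k3


def _unpack_slow(theta: np.ndarray, max_protons: float):
    th2, th3, p2, p3 = theta
    k2 = math.exp(min(max(th2, -25.0), 25.0))
    k3 = k2 * float(_sigmoid(np.array(th3)))
    w = _softmax(np.array([p2, p3]))
    B, C, NE = max_protons * w
    return 0.0, B, C, NE, math.nan, k2, k3


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def fit_uptake(
    curve: UptakeCurve,
    peptide: PeptideRecord,
    slow_threshold_d: float = 0.5,
    grid_points: int = _DEFAULT_GRID_POINTS,
) -> ExchangeFit:
    """Fit the constrained exponential-sum model to an uptake curve.

    Unweighted least squares over all timepoints; exponential-sum fits are
    multi-modal, so the optimizer is restarted from every strictly ordered
    rate triple on a log-spaced grid (1e-5 to 1 /s, ``grid_points`` points)
    with an even amplitude split, and the best start by residual sum of
    squares wins.

    Slow peptides -- replicate-mean uptake below ``slow_threshold_d``
    deuterons at the final timepoint -- are fit with the fast term removed.
    """
    grid = np.logspace(-5, 0, grid_points)
    t = curve.timepoints_s
    d = curve.mean_d
    P = float(peptide.max_protons)
    if P <= 0:
        raise ValueError("cannot fit a peptide with no exchangeable protons")
    n_nonzero = int(np.sum(t > 0))
    under_determined = n_nonzero < 4

    slow = bool(d[np.argmax(t)] < slow_threshold_d)

    if slow:
        def resid(theta):
            _, B, C, NE, _, k2, k3 = _unpack_slow(theta, P)
            return predict_uptake(t, 0.0, B, C, math.nan, k2, k3) - d

        starts = []
        for k2_0 in grid[:-1]:
            for k3_0 in grid[grid < k2_0]:
                starts.append(np.array([math.log(k2_0), _logit(k3_0 / k2_0), 0.0, 0.0]))
        unpack = _unpack_slow
    else:
        def resid(theta):
            A, B, C, NE, k1, k2, k3 = _unpack_full(theta, P)
            return predict_uptake(t, A, B, C, k1, k2, k3) - d

        starts = []
        for i in range(len(grid)):
            for j in range(i):
                for l in range(j):
                    k1_0, k2_0, k3_0 = grid[i], grid[j], grid[l]
                    starts.append(np.array([
                        math.log(k1_0), _logit(k2_0 / k1_0), _logit(k3_0 / k2_0),
                        0.0, 0.0, 0.0,
                    ]))
        unpack = _unpack_full

    # an essentially exact fit ends the multi-start early; degenerate curves
    # (fewer distinct kinetic phases than model terms) otherwise burn the
    # whole evaluation budget polishing an unidentifiable direction
    exact_rss = 1e-16 * len(t) * P ** 2
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=1000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
        if best[0] < exact_rss:
            break

    if best is None:
        return ExchangeFit(
            peptide_id=curve.peptide_id, state=curve.state,
            A=math.nan, B=math.nan, C=math.nan, NE=math.nan,
            k1=math.nan, k2=math.nan, k3=math.nan,
            rss=math.nan, modified_slow_fit=slow, fit_ok=False,
            max_protons=peptide.max_protons,
        )

    rss, theta = best
    A, B, C, NE, k1, k2, k3 = unpack(theta, P)
    return ExchangeFit(
        peptide_id=curve.peptide_id, state=curve.state,
        A=A, B=B, C=C, NE=NE, k1=k1, k2=k2, k3=k3,
        rss=rss, modified_slow_fit=slow,
        fit_ok=not under_determined,
        max_protons=peptide.max_protons,
    )


@dataclass
class BackExchangeSummary:
    """Cohort summary of fully-deuterated control recoveries."""

    mean_pct: float
    sd_pct: float
    flagged_pct: float          # share of peptides at or below the threshold
    n_flagged: int
    n_total: int
    threshold: float = 0.50


def backexchange_summary(
    fd_fractions: Sequence[float],
    threshold: float = 0.50,
) -> BackExchangeSummary:
    """Summarise per-peptide fully-deuterated recoveries.

    ``fd_fractions`` are FD-control deuteration levels as fractions of each
    peptide's amide budget (1 - back-exchange loss); values in (0, 1.2]
    (slack for noise).  Reports mean and SD as percentages and the fraction
    of peptides at or below ``threshold``, with numerator and denominator.
    """
    fr = np.asarray(list(fd_fractions), dtype=float)
    if fr.size == 0:
        raise ValueError("no FD fractions supplied")
    if np.any(fr <= 0) or np.any(fr > 1.2):
        raise ValueError("FD fractions must lie in (0, 1.2]")
    n_flag = int(np.sum(fr <= threshold))
    return BackExchangeSummary(
        mean_pct=float(fr.mean() * 100.0),
        sd_pct=float(fr.std(ddof=0) * 100.0),
        flagged_pct=100.0 * n_flag / fr.size,
        n_flagged=n_flag,
        n_total=int(fr.size),
        threshold=threshold,
    )


def fit_all_peptides(
    centroids: pd.DataFrame,
    peptides: Sequence[PeptideRecord],
    states: Sequence[str],
) -> pd.DataFrame:
    """Fit every peptide/state combination present in a centroid table.

    Returns the per-peptide fit table (one row per peptide/state) with the
    columns of the on-disk schema.
    """
    rows = []
    by_id = {p.peptide_id: p for p in peptides}
    present = set(centroids["peptide_id"].unique())
    for pid, pep in by_id.items():
        if pid not in present or pep.max_protons <= 0:
            continue
        for state in states:
            sub = centroids[
                (centroids["peptide_id"] == pid) & (centroids["state"] == state)
            ]
            if sub.empty:
                continue
            curve = build_uptake_curve(centroids, pep, state)
            fit = fit_uptake(curve, pep)
            rows.append({
                "peptide_id": pid, "state": state,
                "A": fit.A, "B": fit.B, "C": fit.C, "NE": fit.NE,
                "k1": fit.k1, "k2": fit.k2, "k3": fit.k3,
                "rss": fit.rss,
                "modified_slow_fit": fit.modified_slow_fit,
                "fit_ok": fit.fit_ok,
            })
    return pd.DataFrame(rows)
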