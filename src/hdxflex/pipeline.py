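"""End-to-end orchestration: simulate -> fit -> diff -> classify -> enrich -> waters.

Stages communicate through CSV/FASTA/PDB files in a run directory and a
JSON manifest records the seed, configuration, per-stage row counts and
content hashes, so any output is reproducible from the manifest alone.
All randomness is funneled through the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, uptake, differential, phenotype, waters
from .synthetic import SynthConfig, GroundTruth
from .uptake import PeptideRecord

__all__ = [
    "RunConfig",
    "PipelineError",
    "STAGES",
    "run_pipeline",
    "peptides_from_centroids",
    "truth_region_directions",
]

logger = logging.getLogger("hdxflex")

STAGES = ("simulate", "fit", "diff", "classify", "enrich", "waters")

#: files each stage requires (produced by earlier stages)
_STAGE_INPUTS = {
    "simulate": (),
    "fit": ("centroids.csv", "protein.fasta"),
    "diff": ("centroids.csv", "uptake_curves.csv"),
    "classify": ("differences.csv", "centroids.csv", "protein.fasta"),
    "enrich": ("flexmap.csv", "phenotypes.csv"),
    "waters": ("ensemble.pdb",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple = STAGES
    synth: SynthConfig = field(default_factory=SynthConfig)
    state1: str = "IPTG"
    state2: str = "DNA"
    threshold: float = differential.DEFAULT_THRESHOLD
    min_timepoints: int = differential.DEFAULT_MIN_TIMEPOINTS
    p_concordant: float = 0.9
    region_filter: tuple | None = None
    n_structures: int = 20
    n_planted_waters: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "synth" in d:
            sd = d["synth"]
            if "cleavage_residues" in sd:
                sd["cleavage_residues"] = frozenset(sd["cleavage_residues"])
            for k in ("timepoints_s", "states"):
                if k in sd:
                    sd[k] = tuple(sd[k])
            d["synth"] = SynthConfig(**sd)
        for k in ("stages", "region_filter"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def peptides_from_centroids(centroids: pd.DataFrame) -> list[PeptideRecord]:
    """Rebuild peptide records from centroid-table identity columns."""
    seen = centroids[["peptide_id", "sequence", "start"]].drop_duplicates("peptide_id")
    return [
        PeptideRecord.from_sequence(row.sequence, int(row.start), row.peptide_id)
        for row in seen.itertuples()
    ]


def truth_region_directions(
    truth: GroundTruth,
    peptides,
    config: SynthConfig,
    threshold: float = differential.DEFAULT_THRESHOLD,
    min_timepoints: int = differential.DEFAULT_MIN_TIMEPOINTS,
) -> dict:
    """Residue -> more-rigid state, from the noise-free ground truth at
    peptide-level resolution.

    Applies the same thresholded classification rule to the exact uptake
    curves implied by the planted classes: this is the residue-region map a
    noiseless experiment would report, and the natural planting target for
    phenotype labels (phenotype data reflect regions, which peptide-level
    measurements resolve to peptide footprints).
    """
    s1, s2 = truth.states[0], truth.states[1]
    tps = np.asarray(config.timepoints_s, dtype=float)
    diffs = []
    for pep in peptides:
        if pep.max_protons < 1:
            continue
        d1 = synthetic.true_uptake(truth, pep, s1, tps)
        d2 = synthetic.true_uptake(truth, pep, s2, tps)
        c1 = uptake.UptakeCurve(pep.peptide_id, s1, tps, d1, np.zeros_like(tps),
                                np.ones_like(tps, dtype=int), pep.max_protons)
        c2 = uptake.UptakeCurve(pep.peptide_id, s2, tps, d2, np.zeros_like(tps),
                                np.ones_like(tps, dtype=int), pep.max_protons)
        diffs.append(differential.fractional_difference(c1, c2, pep))
    fmap = differential.classify_residues(
        diffs, peptides, threshold, min_timepoints, n_residues=len(truth.sequence)
    )
    out = {}
    for r, rl in fmap.labels.items():
        if rl.label == "more_rigid_in_state1":
            out[r] = s1
        elif rl.label == "more_rigid_in_state2":
            out[r] = s2
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _row_count(path: Path) -> int | None:
    if path.suffix == ".csv":
        return sum(1 for _ in open(path)) - 1
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=_json_default)),
        "stages": {},
    }

    for stage in config.stages:
        missing = [f for f in _STAGE_INPUTS[stage] if not (out / f).exists()]
        if missing:
            raise PipelineError(
                f"stage {stage!r} requires outputs of earlier stages: missing {missing}"
            )
        t0 = time.monotonic()
        produced = _STAGE_RUNNERS[stage](config, out)
        elapsed = time.monotonic() - t0
        info = {
            "elapsed_s": round(elapsed, 3),
            "outputs": {
                f: {"sha256": _sha256(out / f), "rows": _row_count(out / f)}
                for f in produced
            },
        }
        manifest["stages"][stage] = info
        logger.info("stage %s done in %.2fs: %s", stage, elapsed, ", ".join(produced))

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _json_default(o):
    if isinstance(o, frozenset):
        return sorted(o)
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o).__name__)


# --------------------------------------------------------------------------
# stage runners


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    synth = config.synth
    synth.seed = config.seed if synth.seed == 0 else synth.seed
    synth.states = (config.state1, config.state2)
    truth = synthetic.generate_ground_truth(synth)
    peptides = synthetic.digest(truth.sequence, synth)
    centroids = synthetic.simulate_centroids(truth, peptides, synth)
    directions = truth_region_directions(
        truth, peptides, synth, config.threshold, config.min_timepoints
    )
    phenos = synthetic.generate_phenotypes(
        truth, config.p_concordant, seed=config.seed + 7, directions=directions
    )
    ensemble = synthetic.generate_toy_ensemble(
        config.n_structures, config.n_planted_waters, seed=config.seed + 11
    )
    synthetic.write_fasta(truth.sequence, out / "protein.fasta")
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    centroids.to_csv(out / "centroids.csv", index=False)
    phenos.to_csv(out / "phenotypes.csv", index=False)
    waters.write_ensemble_pdb(ensemble, out / "ensemble.pdb")
    synth.to_json(out / "synth_config.json")
    return ["protein.fasta", "ground_truth.csv", "centroids.csv",
            "phenotypes.csv", "ensemble.pdb", "synth_config.json"]


def _curves_for(centroids, peptides, states):
    curves = {}
    for pep in peptides:
        if pep.max_protons < 1:
            continue
        for state in states:
            sub = centroids[(centroids["peptide_id"] == pep.peptide_id)
                            & (centroids["state"] == state)]
            if sub.empty:
                continue
            curves[(pep.peptide_id, state)] = uptake.build_uptake_curve(
                centroids, pep, state
            )
    return curves


def _stage_fit(config: RunConfig, out: Path) -> list[str]:
    centroids = pd.read_csv(out / "centroids.csv")
    peptides = peptides_from_centroids(centroids)
    states = [config.state1, config.state2]
    fits = uptake.fit_all_peptides(centroids, peptides, states)
    fits.to_csv(out / "fits.csv", index=False)
    rows = []
    for (pid, state), c in _curves_for(centroids, peptides, states).items():
        for i, t in enumerate(c.timepoints_s):
            rows.append({"peptide_id": pid, "state": state, "timepoint_s": t,
                         "mean_d": c.mean_d[i], "sd_d": c.sd_d[i],
                         "n": int(c.n_replicates[i])})
    pd.DataFrame(rows).to_csv(out / "uptake_curves.csv", index=False)
    return ["fits.csv", "uptake_curves.csv"]


def _stage_diff(config: RunConfig, out: Path) -> list[str]:
    centroids = pd.read_csv(out / "centroids.csv")
    peptides = peptides_from_centroids(centroids)
    curated = differential.curate_peptides(
        centroids, [config.state1, config.state2], require_fd=True,
        min_replicates=min(2, config.synth.n_replicates),
    )
    curves = _curves_for(centroids, peptides, [config.state1, config.state2])
    frames = []
    for pep in peptides:
        if pep.peptide_id not in curated:
            continue
        key1, key2 = (pep.peptide_id, config.state1), (pep.peptide_id, config.state2)
        if key1 in curves and key2 in curves:
            frames.append(differential.fractional_difference(
                curves[key1], curves[key2], pep).to_frame())
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["peptide_id", "state1", "state2", "timepoint_s",
                 "delta_hx", "uncertainty"])
    df.to_csv(out / "differences.csv", index=False)
    return ["differences.csv"]


def _stage_classify(config: RunConfig, out: Path) -> list[str]:
    diffs_df = pd.read_csv(out / "differences.csv")
    centroids = pd.read_csv(out / "centroids.csv")
    peptides = peptides_from_centroids(centroids)
    sequence = synthetic.read_fasta(out / "protein.fasta")
    diffs = []
    for pid, grp in diffs_df.groupby("peptide_id"):
        grp = grp.sort_values("timepoint_s")
        diffs.append(differential.FractionalDifference(
            peptide_id=pid,
            state1=str(grp["state1"].iloc[0]), state2=str(grp["state2"].iloc[0]),
            timepoints_s=grp["timepoint_s"].to_numpy(),
            delta_hx=grp["delta_hx"].to_numpy(),
            uncertainty=grp["uncertainty"].to_numpy(),
        ))
    fmap = differential.classify_residues(
        diffs, peptides, config.threshold, config.min_timepoints,
        n_residues=len(sequence),
    )
    differential.write_flexmap_csv(fmap, out / "flexmap.csv")
    differential.write_flexmap_bed(fmap, out / "flexmap.bed")
    return ["flexmap.csv", "flexmap.bed"]


def _stage_enrich(config: RunConfig, out: Path) -> list[str]:
    fdf = pd.read_csv(out / "flexmap.csv")
    labels = {
        int(r.residue): differential.ResidueLabel(r.label)
        for r in fdf.itertuples()
    }
    fmap = differential.ResidueFlexMap(
        config.state1, config.state2, labels, config.threshold, config.min_timepoints
    )
    phenos = pd.read_csv(out / "phenotypes.csv")
    table = phenotype.enrichment(fmap, phenos, region_filter=config.region_filter)
    table.to_frame().to_csv(out / "enrichment.csv", index=False)
    (out / "enrichment.txt").write_text(table.format_text() + "\n")
    return ["enrichment.csv", "enrichment.txt"]


def _stage_waters(config: RunConfig, out: Path) -> list[str]:
    ensemble = waters.read_ensemble(out / "ensemble.pdb")
    pmap = waters.hbond_probability(ensemble)
    pmap.table.to_csv(out / "water_probabilities.csv", index=False)
    return ["water_probabilities.csv"]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "diff": _stage_diff,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "waters": _stage_waters,
}
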