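"""End-to-end orchestration: distances → clustering → validity → classification.

A run executes, in dependency order and for a single aligned FASTA:

1. pairwise p-distance matrix (pairwise deletion);
2. the five clustering algorithms and their consensus;
3. validity curves (SSE / silhouette / gap) and the cluster-number choice;
4. group-label assignment — user-supplied labels win; otherwise the
   consensus partition is used, with the cluster containing a designated
   reference sequence (or, absent one, the smaller cluster) flagged as the
   putative cryptic group;
5. stratified cross-validation of RF/SVM/MLP, all-sample random-forest
   site importance, key-site tables and logo data.

Every stage writes TSV/JSON artifacts into the output directory, and a
manifest records parameters, seeds and input checksums so any run is fully
reconstructible.  All stage outputs are pure functions of their inputs and
the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import cluster as _cluster
from . import validity as _validity
from .distances import distance_matrix, group_distance_sets
from .seqio import (
    Alignment,
    encode_ordinal,
    read_alignment,
    read_labels,
    write_labels,
)

log = logging.getLogger("mitodelim")

ALL_STAGES = ("pdist", "cluster", "validity", "classify", "importance", "report")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input: str | Path
    output_dir: str | Path
    labels: str | Path | None = None
    reference_id: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    k: int = 2
    k_range: tuple[int, ...] = tuple(range(1, 9))
    seed: int = 0
    folds: int = 5
    nmf_nrun: int = 1000
    gap_b: int = 100
    dbscan_eps: float = 0.5
    dbscan_min_pts: int = 20
    key_site_thresholds: tuple[float, ...] = (0.0, 0.1)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


@dataclass
class RunResult:
    """In-memory handles to the artifacts of one run."""

    config: RunConfig
    alignment: Alignment
    dm: object = None
    consensus: object = None
    curve: object = None
    k_best: int | None = None
    per_criterion: dict = field(default_factory=dict)
    labels: np.ndarray | None = None
    focal_group: int | None = None
    cv: object = None
    importance: object = None
    key_sites: dict = field(default_factory=dict)
    logo: object = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _assign_labels(res: RunResult, cfg: RunConfig) -> np.ndarray:
    """Binary class labels for the classifier stage.

    Priority: user-supplied labels; else the consensus partition.  When a
    reference id is given its consensus cluster defines the focal
    (putative-cryptic) class; otherwise the smaller cluster is flagged.
    """
    aln = res.alignment
    if aln.labels is not None:
        classes = sorted(set(aln.labels))
        if len(classes) != 2:
            raise ValueError(
                f"classification needs exactly 2 groups, got {len(classes)}"
            )
        return np.array([classes.index(lab) for lab in aln.labels])
    if res.consensus is None:
        raise ValueError(
            "classify stage needs labels or an upstream clustering stage"
        )
    cons = np.asarray(res.consensus.consensus_labels)
    clusters = [c for c in np.unique(cons) if c >= 0]
    if len(clusters) != 2:
        raise ValueError(
            f"consensus produced {len(clusters)} clusters; classification "
            "requires 2 (supply labels to override)"
        )
    if cfg.reference_id is not None:
        if cfg.reference_id not in aln.ids:
            raise ValueError(f"reference id {cfg.reference_id!r} not in alignment")
        focal = int(cons[aln.ids.index(cfg.reference_id)])
    else:  # smaller cluster flagged for review as the putative cryptic group
        sizes = {c: int((cons == c).sum()) for c in clusters}
        focal = min(sizes, key=lambda c: (sizes[c], c))
    res.focal_group = focal
    return (cons == focal).astype(int)


def run(config: RunConfig) -> RunResult:
    """Execute the configured stages; artifacts land in ``output_dir``."""
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inpath = Path(config.input)
    aln = read_alignment(inpath)
    if config.labels is not None:
        aln = aln.with_labels(read_labels(config.labels))
    res = RunResult(config=config, alignment=aln)
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "input_sha256": _sha256(inpath),
        "n_sequences": aln.n,
        "n_columns": aln.length,
        "stages": {},
    }
    stages = set(config.stages)
    need_dist = stages & {"pdist", "cluster", "validity", "report"}

    def _stage(name: str, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        fn()
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s: done in %.2fs", name, time.time() - t0)

    if need_dist:
        def do_pdist():
            res.dm = distance_matrix(aln)
            res.dm.write_tsv(outdir / "pdistance_matrix.tsv")
            res.dm.to_long_frame().to_csv(
                outdir / "pdistance_pairs.tsv", sep="\t", index=False
            )
            if aln.labels is not None:
                gs = group_distance_sets(
                    res.dm, dict(zip(aln.ids, aln.labels))
                )
                with open(outdir / "group_distances.json", "w") as fh:
                    json.dump(
                        {
                            "averages": _jsonable(
                                {str(k): v for k, v in gs.averages.items()}
                            )
                        },
                        fh,
                        indent=2,
                    )
        _stage("pdist", do_pdist)

    if "cluster" in stages:
        def do_cluster():
            res.consensus = _cluster.cluster_all(
                res.dm,
                k=config.k,
                seed=config.seed,
                nmf_nrun=config.nmf_nrun,
                dbscan_eps=config.dbscan_eps,
                dbscan_min_pts=config.dbscan_min_pts,
            )
            for r in res.consensus.per_algorithm:
                write_labels(
                    aln.ids, r.labels.tolist(),
                    outdir / f"clusters_{r.algorithm}.tsv",
                )
            write_labels(
                aln.ids,
                res.consensus.consensus_labels.tolist(),
                outdir / "clusters_consensus.tsv",
            )
        _stage("cluster", do_cluster)

    if "validity" in stages:
        def do_validity():
            res.curve = _validity.validity_curve(
                res.dm,
                k_range=config.k_range,
                b=config.gap_b,
                seed=config.seed,
            )
            res.curve.write_tsv(outdir / "validity_curve.tsv")
            res.k_best, res.per_criterion = _validity.choose_k(res.curve)
            with open(outdir / "k_choice.json", "w") as fh:
                json.dump(
                    {"k_best": res.k_best,
                     "per_criterion": _jsonable(res.per_criterion)},
                    fh, indent=2,
                )
        _stage("validity", do_validity)

    if stages & {"classify", "importance", "report"}:
        res.labels = _assign_labels(res, config)
        enc = encode_ordinal(aln)

        if "classify" in stages:
            def do_classify():
                res.cv = _classify.cross_validate(
                    enc, res.labels, folds=config.folds, seed=config.seed
                )
                res.cv.to_frame().to_csv(
                    outdir / "cv_metrics.tsv", sep="\t", index=False
                )
                with open(outdir / "cv_summary.json", "w") as fh:
                    json.dump(
                        {
                            "mean_auc": _jsonable(res.cv.mean_auc),
                            "sd_auc": _jsonable(res.cv.sd_auc),
                            "confusion": _jsonable(res.cv.confusion),
                        },
                        fh, indent=2,
                    )
            _stage("classify", do_classify)

        if "importance" in stages:
            def do_importance():
                res.importance = _classify.feature_importance(
                    enc, res.labels, seed=config.seed
                )
                res.importance.write_tsv(outdir / "importance.tsv")
                res.key_sites = _classify.key_sites(
                    res.importance, config.key_site_thresholds
                )
                with open(outdir / "key_sites.json", "w") as fh:
                    json.dump(_jsonable(res.key_sites), fh, indent=2)
            _stage("importance", do_importance)

        if "report" in stages:
            def do_report():
                if res.importance is None:
                    res.importance = _classify.feature_importance(
                        enc, res.labels, seed=config.seed
                    )
                res.logo = _classify.logo_data(aln, res.importance)
                res.logo.to_csv(outdir / "logo_data.tsv", sep="\t", index=False)
            _stage("report", do_report)

    manifest["wall_seconds"] = round(time.time() - t_start, 3)
    res.manifest = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return res
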