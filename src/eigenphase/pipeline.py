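"""End-to-end orchestration: preprocess -> stratify -> align -> lag -> interpret.

Driven by a single YAML config in which every analysis constant is an
explicit key, so that the defaults declared by each module are visible and
overridable in one place. Outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, alignment, eigen, interpret, io, lags

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DatasetEntry", "run_pipeline", "load_config"]

ANALYSIS_DEFAULTS = {
    "log_transform": False,
    "pseudocount": 1.0,
    "normalize": True,
    "qc_tolerance": 0.1,
    "levels": [1, 2],
    "resolution": 0.001,
    "max_lag": 1.5,
    "min_overlap": 0.5,
    "lag_reps": 1000,
    "lag_fraction": 0.10,
    "marker_reps": 0,  # 0 disables marker randomization
    "marker_level": 1,
    "p_max": 0.01,
    "enrich_min_size": 5,
    "gmt": None,
    "contributions_for": [],  # dataset labels to decompose against the reference phases
    "seed": 0,
}


@dataclass
class DatasetEntry:
    label: str
    matrix: Path
    metadata: Path
    oxygen: Path | None = None
    role: str = "query"  # "reference" or "query"


@dataclass
class PipelineConfig:
    datasets: list[DatasetEntry]
    analysis: dict = field(default_factory=dict)
    outdir: Path = Path("eigenphase_out")

    def __post_init__(self) -> None:
        refs = [d for d in self.datasets if d.role == "reference"]
        if len(refs) != 1:
            raise ValueError(f"exactly one reference dataset required, found {len(refs)}")
        for d in self.datasets:
            for p in (d.matrix, d.metadata, d.oxygen):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"missing input file for {d.label!r}: {p}")
        merged = dict(ANALYSIS_DEFAULTS)
        merged.update(self.analysis)
        self.analysis = merged

    @property
    def reference(self) -> DatasetEntry:
        return next(d for d in self.datasets if d.role == "reference")


def load_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    datasets = [
        DatasetEntry(
            label=d["label"],
            matrix=base / d["matrix"],
            metadata=base / d["metadata"],
            oxygen=(base / d["oxygen"]) if d.get("oxygen") else None,
            role=d.get("role", "query"),
        )
        for d in doc["datasets"]
    ]
    return PipelineConfig(
        datasets=datasets,
        analysis=doc.get("analysis", {}),
        outdir=base / doc.get("outdir", "eigenphase_out"),
    )


def _preprocess(entry: DatasetEntry, opts: dict) -> io.OmicsMatrix:
    mat = io.read_omics_table(entry.matrix, entry.metadata, omics_label=entry.label)
    if opts["log_transform"] and not mat.provenance.get("log_transformed"):
        mat = io.log_transform(mat, opts["pseudocount"])
    if opts["normalize"]:
        ref = io.select_reference_sample(mat)
        mat = io.normalize_to_reference(mat, ref)
    return mat


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured datasets and write a summary.

    Per dataset: preprocessing, SVD stratification, contribution/entropy and
    phase calls. Across datasets: DDTW timeline alignment of oxygen curves,
    per-pair lag estimates with perturbation CIs against the reference, and
    (optionally) enrichment, marker randomization and phase-contribution
    decomposition. Returns the summary dict and writes ``summary.json``.
    """
    opts = config.analysis
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(opts["seed"])
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in opts.items()},
        "datasets": {},
        "lags": [],
    }

    mats: dict[str, io.OmicsMatrix] = {}
    decs: dict[str, eigen.EigenDecomposition] = {}
    for entry in config.datasets:
        try:
            mat = _preprocess(entry, opts)
            dec = eigen.stratify(mat)
            contrib = eigen.relative_contributions(dec)
            phases = eigen.call_phases(dec)
            diag = eigen.baseline_diagnostics(dec)
            qc = io.qc_pairwise_modes(mat, tolerance=opts["qc_tolerance"])
        except Exception as exc:
            raise RuntimeError(f"stage 'decompose' failed for dataset {entry.label!r}: {exc}") from exc
        mats[entry.label] = mat
        decs[entry.label] = dec
        dec.to_dir(outdir / f"decomposition_{entry.label}")
        phases.table.to_csv(outdir / f"phases_{entry.label}.tsv", sep="\t", index=False)
        summary["datasets"][entry.label] = {
            "n_molecules": mat.m,
            "n_samples": mat.n,
            "contributions": {
                str(k): float(p) for k, p in zip(contrib.level_indices, contrib.ratios)
            },
            "top_two_contribution": contrib.top_two(),
            "eigen_entropy": contrib.eigen_entropy,
            "normalized_entropy": contrib.normalized_entropy,
            "baseline_ok": bool(diag["passed"]),
            "qc_all_passed": bool(qc["passed"].all()),
            "cyclic_order": phases.cyclic_order,
        }

    ref = config.reference
    ref_curve = None
    if ref.oxygen is not None:
        ref_curve = alignment.resample_uniform(io.read_curve(ref.oxygen, ref.label))
    timelines: dict[str, alignment.UnifiedTimeline] = {}
    for entry in config.datasets:
        if entry.role == "reference" or entry.oxygen is None or ref_curve is None:
            continue
        try:
            q_curve = alignment.resample_uniform(io.read_curve(entry.oxygen, entry.label))
            path = alignment.ddtw_align(ref_curve, q_curve)
            tl = alignment.map_sample_times(
                path, ref_curve, q_curve, mats[entry.label].sample_times, entry.label
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'align' failed for dataset {entry.label!r}: {exc}") from exc
        timelines[entry.label] = tl
        np.savetxt(
            outdir / f"warp_{entry.label}.tsv",
            np.asarray(path.pairs, dtype=int),
            fmt="%d",
            delimiter="\t",
            header="ref_index\tquery_index",
            comments="",
        )

    levels = tuple(int(k) for k in opts["levels"])
    for entry in config.datasets:
        if entry.role == "reference":
            continue
        try:
            ests = lags.lag_ci(
                decs[entry.label],
                decs[ref.label],
                timeline=timelines.get(entry.label),
                levels=levels,
                R=int(opts["lag_reps"]),
                fraction=float(opts["lag_fraction"]),
                seed=seed + zlib.crc32(entry.label.encode()) % 10007,
                resolution=float(opts["resolution"]),
                max_lag=float(opts["max_lag"]),
                min_overlap=float(opts["min_overlap"]),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'lag' failed for dataset {entry.label!r}: {exc}") from exc
        summary["lags"].extend(e.to_dict() for e in ests)

    if opts["gmt"]:
        sets = io.read_gmt(opts["gmt"])
        dec = decs[ref.label]
        enr = {}
        for k in levels:
            series = pd.Series(dec.level(k).molecule_loadings, index=dec.molecule_ids)
            table = interpret.wilcoxon_enrich(series, sets, min_size=int(opts["enrich_min_size"]))
            table.to_csv(outdir / f"enrichment_level{k}.tsv", sep="\t", index=False)
            enr[str(k)] = int((table["q"] <= 0.05).sum())
        summary["enrichment_sets_q05"] = enr

    if int(opts["marker_reps"]) > 0:
        k = int(opts["marker_level"])
        results = interpret.marker_randomization(
            mats[ref.label],
            decs[ref.label],
            k,
            R=int(opts["marker_reps"]),
            seed=seed + 1,
            p_max=float(opts["p_max"]),
        )
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            outdir / f"markers_level{k}.tsv", sep="\t", index=False
        )
        summary["n_markers"] = int(sum(r.is_marker for r in results))

    contribs = {}
    for label in opts["contributions_for"]:
        contribs[label] = interpret.phase_contributions(mats[label], decs[ref.label])
    if contribs:
        summary["phase_contributions"] = contribs

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
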