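"""Reading, writing and preprocessing of omics matrices, indicator curves and gene sets.

The central container is :class:`OmicsMatrix`, a molecule x timed-sample signal
matrix on log scale. Preprocessing covers log transformation, a pluggable
robust normalization against a reference sample (selected by the
sum-of-pairwise-difference-skewness heuristic) and a kernel-density QC of
pairwise difference modes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "IndicatorCurve",
    "read_omics_table",
    "write_omics_table",
    "read_curve",
    "write_curve",
    "read_gmt",
    "write_gmt",
    "select_reference_sample",
    "normalize_to_reference",
    "log_transform",
    "qc_pairwise_modes",
]


@dataclass
class OmicsMatrix:
    """A molecule x sample signal matrix with sample collection times.

    Parameters
    ----------
    values
        Real matrix of shape (m, n); log-scale after preprocessing.
    molecule_ids
        Unique row identifiers (genes, histone-signal genes, metabolites).
    sample_ids
        Unique column identifiers, ordered by ascending collection time.
    sample_times
        Collection time in hours for each sample, strictly increasing.
    omics_label
        Dataset label, e.g. ``"transcriptome"``, ``"H3K9ac"``, ``"metabolome"``.
    provenance
        Processing history: ``log_transformed`` flag, normalization method, ...
    """

    values: np.ndarray
    molecule_ids: list[str]
    sample_ids: list[str]
    sample_times: np.ndarray
    omics_label: str = "omics"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.molecule_ids = list(self.molecule_ids)
        self.sample_ids = list(self.sample_ids)
        m, n = self.values.shape
        if m < 2 or n < 3:
            raise ValueError(f"matrix too small: {m} molecules x {n} samples (need m>=2, n>=3)")
        if len(self.molecule_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.molecule_ids)) != m:
            raise ValueError("duplicate molecule ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.sample_times.shape != (n,):
            raise ValueError("sample_times length does not match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in matrix")
        if not np.all(np.diff(self.sample_times) > 0):
            raise ValueError("sample_times must be strictly increasing")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class IndicatorCurve:
    """A measured indicator time series, e.g. dissolved-oxygen concentration."""

    times: np.ndarray
    values: np.ndarray
    dataset_label: str = "curve"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if self.times.size < 4:
            raise ValueError("curve needs at least 4 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("curve times must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_omics_table(path, meta_path, omics_label: str | None = None) -> OmicsMatrix:
    """Read a molecule x sample table plus sample metadata.

    The table's first column holds molecule ids and the header row the sample
    ids. Metadata must provide ``sample_id`` and ``time_h`` columns (and
    optionally ``dataset_label``). Columns are reordered by ascending time;
    molecules with any missing value are dropped (and logged).
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    meta = pd.read_csv(meta_path, sep=_sep(meta_path))
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate molecule or sample ids in table")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    times = dict(zip(meta["sample_id"].astype(str), meta["time_h"].astype(float)))
    missing = [s for s in df.columns if str(s) not in times]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")

    complete = df.dropna(axis=0)
    dropped = sorted(set(df.index) - set(complete.index))
    if dropped:
        logger.info("dropped %d molecules with missing values: %s", len(dropped), dropped)
    if complete.shape[1] < 3:
        raise ValueError("fewer than 3 complete samples")

    order = sorted(complete.columns, key=lambda s: times[str(s)])
    complete = complete[order]
    label = omics_label
    if label is None:
        label = str(meta["dataset_label"].iloc[0]) if "dataset_label" in meta else "omics"
    return OmicsMatrix(
        values=complete.to_numpy(dtype=float),
        molecule_ids=[str(i) for i in complete.index],
        sample_ids=[str(c) for c in complete.columns],
        sample_times=np.array([times[str(c)] for c in complete.columns]),
        omics_label=label,
        provenance={"source": str(path), "dropped_molecules": dropped},
    )


def write_omics_table(mat: OmicsMatrix, path, meta_path=None) -> None:
    df = mat.to_frame()
    df.index.name = "molecule_id"
    df.to_csv(path, sep=_sep(path), float_format="%.17g")
    if meta_path is not None:
        pd.DataFrame(
            {
                "sample_id": mat.sample_ids,
                "time_h": mat.sample_times,
                "dataset_label": mat.omics_label,
            }
        ).to_csv(meta_path, sep=_sep(meta_path), index=False)


def read_curve(path, dataset_label: str | None = None) -> IndicatorCurve:
    """Read a two-column (time_h, value) TSV/CSV indicator curve."""
    df = pd.read_csv(path, sep=_sep(path))
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    return IndicatorCurve(t, v, dataset_label or str(path))


def write_curve(curve: IndicatorCurve, path) -> None:
    pd.DataFrame({"time_h": curve.times, "value": curve.values}).to_csv(
        path, sep=_sep(path), index=False, float_format="%.17g"
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: set name, description, then member ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def _skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness; 0 for degenerate input."""
    if x.size < 3 or np.ptp(x) == 0 or np.std(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=False))


def select_reference_sample(mat: OmicsMatrix) -> str:
    """Pick the normalization reference: the sample with the largest sum of
    skewness of its pairwise difference vectors.

    For sample ``j``, ``S_j = sum_{j' != j} skew(col_j - col_j')``. Degenerate
    (constant) difference vectors contribute 0 with a warning. Ties break to
    the earliest sample in time order.
    """
    n = mat.n
    scores = np.zeros(n)
    degenerate = False
    for j in range(n):
        for jp in range(n):
            if jp == j:
                continue
            d = mat.values[:, j] - mat.values[:, jp]
            if np.ptp(d) == 0:
                degenerate = True
                continue
            scores[j] += _skewness(d)
    if degenerate:
        warnings.warn("constant pairwise difference vector(s); treated as zero skewness")
    best = int(np.argmax(scores))  # argmax returns the first maximum: earliest in time
    return mat.sample_ids[best]


def normalize_to_reference(mat: OmicsMatrix, ref: str) -> OmicsMatrix:
    """Median-of-differences normalization on the log scale.

    Each column j is shifted by ``-median(col_j - col_ref)`` so that the
    per-pair difference to the reference has median zero. One robust location
    shift per sample; the method name is recorded in provenance so a different
    normalizer can be plugged in.
    """
    if ref not in mat.sample_ids:
        raise ValueError(f"unknown reference sample {ref!r}")
    ref_col = mat.column(ref)
    shifts = np.median(mat.values - ref_col[:, None], axis=0)
    prov = dict(mat.provenance)
    prov["normalization"] = "median_of_differences"
    prov["reference_sample"] = ref
    return replace(mat, values=mat.values - shifts[None, :], provenance=prov)


def log_transform(mat: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """log2(value + pseudocount); applicable at most once per matrix."""
    if mat.provenance.get("log_transformed"):
        raise ValueError("matrix is already log-transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(mat.values < 0):
        raise ValueError("negative values: log transform expects raw non-negative signal")
    prov = dict(mat.provenance)
    prov["log_transformed"] = True
    prov["pseudocount"] = pseudocount
    return replace(mat, values=np.log2(mat.values + pseudocount), provenance=prov)


def qc_pairwise_modes(
    mat: OmicsMatrix, tolerance: float = 0.1, grid_size: int = 512
) -> pd.DataFrame:
    """Mode of the per-molecule difference density for every sample pair.

    Well-normalized log-scale data has near-zero modes. Gaussian KDE with
    Silverman bandwidth on a fixed grid spanning the observed difference
    range; a pair passes when ``|mode| <= tolerance``.
    """
    if mat.m < 10:
        warnings.warn("fewer than 10 molecules: pairwise difference density is unstable")
    rows = []
    for j in range(mat.n):
        for jp in range(j + 1, mat.n):
            d = mat.values[:, j] - mat.values[:, jp]
            if np.ptp(d) == 0:
                mode = float(d[0])
            else:
                grid = np.linspace(d.min(), d.max(), grid_size)
                kde = stats.gaussian_kde(d, bw_method="silverman")
                mode = float(grid[np.argmax(kde(grid))])
            rows.append(
                {
                    "sample_1": mat.sample_ids[j],
                    "sample_2": mat.sample_ids[jp],
                    "mode": mode,
                    "passed": abs(mode) <= tolerance,
                }
            )
    return pd.DataFrame(rows)
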