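"""Unified-timeline construction by derivative dynamic time warping (DDTW).

Each dataset carries an indicator curve (dissolved-oxygen concentration vs
time) tracking the same underlying metabolic cycle on its own clock. DDTW
aligns a query curve to a reference curve by dynamic programming on local
derivative estimates, which tracks the *shape* of the traces and is robust
to amplitude differences. Sample collection times are then carried through
the warp path onto the reference timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import IndicatorCurve, OmicsMatrix

__all__ = [
    "WarpPath",
    "UnifiedTimeline",
    "ddtw_derivative",
    "ddtw_align",
    "resample_uniform",
    "map_sample_times",
    "merge_metabolome",
]


@dataclass
class WarpPath:
    """Monotone alignment between two curves' indices."""

    pairs: list[tuple[int, int]]  # (reference index, query index)
    total_cost: float

    def __post_init__(self) -> None:
        i0, j0 = self.pairs[0]
        if (i0, j0) != (0, 0):
            raise ValueError("warp path must start at (0, 0)")
        for (i, j), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            di, dj = i2 - i, j2 - j
            if (di, dj) not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"invalid warp step ({di}, {dj})")

    def query_to_ref(self, n_query: int) -> np.ndarray:
        """Mean reference index paired with each query index."""
        sums = np.zeros(n_query)
        counts = np.zeros(n_query)
        for i, j in self.pairs:
            sums[j] += i
            counts[j] += 1
        return sums / counts


@dataclass
class UnifiedTimeline:
    """Per-dataset sample times mapped onto the reference dataset's clock."""

    reference_label: str
    datasets: dict  # label -> {"original_times": array, "mapped_times": array}

    def mapped(self, label: str) -> np.ndarray:
        return self.datasets[label]["mapped_times"]


def ddtw_derivative(curve: IndicatorCurve | np.ndarray) -> np.ndarray:
    """Local derivative estimate on the index scale.

    Interior points use d_i = ((x_i - x_{i-1}) + (x_{i+1} - x_{i-1}) / 2) / 2,
    the average of the left slope and the centered two-point slope; both
    endpoints copy their adjacent interior estimate. Exact for affine series.
    """
    x = curve.values if isinstance(curve, IndicatorCurve) else np.asarray(curve, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for derivative estimation")
    d = np.empty_like(x)
    d[1:-1] = ((x[1:-1] - x[:-2]) + (x[2:] - x[:-2]) / 2.0) / 2.0
    d[0] = d[1]
    d[-1] = d[-2]
    return d


def resample_uniform(curve: IndicatorCurve, step: float | None = None) -> IndicatorCurve:
    """Linearly resample a curve to a uniform grid (default: median spacing).

    DDTW derivatives live on the index scale, so near-uniform sampling is
    assumed; apply this first when a curve's grid is irregular.
    """
    if step is None:
        step = float(np.median(np.diff(curve.times)))
    t0, t1 = curve.span
    grid = np.arange(t0, t1 + step / 2, step)
    grid = grid[grid <= t1 + 1e-12]
    return IndicatorCurve(grid, np.interp(grid, curve.times, curve.values), curve.dataset_label)


def ddtw_align(ref: IndicatorCurve, query: IndicatorCurve) -> WarpPath:
    """Derivative dynamic time warping of a query curve onto a reference.

    Minimizes the summed squared difference of derivative estimates over
    monotone paths with steps (1,1), (1,0), (0,1), full boundary conditions
    and no window constraint. Ties prefer the diagonal step, then advancing
    the reference, then the query — a deterministic warp for exact ties.
    """
    dr = ddtw_derivative(ref)
    dq = ddtw_derivative(query)
    nr, nq = dr.size, dq.size
    local = (dr[:, None] - dq[None, :]) ** 2
    D = np.full((nr, nq), np.inf)
    step = np.zeros((nr, nq), dtype=np.int8)  # 0=diag, 1=up(i-1), 2=left(j-1)
    D[0, 0] = local[0, 0]
    D[1:, 0] = np.cumsum(local[1:, 0]) + local[0, 0]
    step[1:, 0] = 1
    D[0, 1:] = np.cumsum(local[0, 1:]) + local[0, 0]
    step[0, 1:] = 2
    for i in range(1, nr):
        for j in range(1, nq):
            options = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            best = int(np.argmin(options))  # argmin keeps the first: diag > up > left
            D[i, j] = local[i, j] + options[best]
            step[i, j] = best
    pairs = [(nr - 1, nq - 1)]
    i, j = nr - 1, nq - 1
    while (i, j) != (0, 0):
        s = step[i, j]
        if s == 0 and i > 0 and j > 0:
            i, j = i - 1, j - 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(pairs=pairs, total_cost=float(D[nr - 1, nq - 1]))


def map_sample_times(
    path: WarpPath,
    ref: IndicatorCurve,
    query: IndicatorCurve,
    query_sample_times: np.ndarray,
    dataset_label: str | None = None,
) -> UnifiedTimeline:
    """Carry sample times of the query dataset onto the reference timeline.

    Each sample time is located on the query index axis by linear
    interpolation, pushed through the warp path (reference indices paired
    with one query index are averaged), and converted back to reference time
    by linear interpolation of the reference time grid.
    """
    ts = np.asarray(query_sample_times, dtype=float)
    lo, hi = query.span
    bad = ts[(ts < lo - 1e-9) | (ts > hi + 1e-9)]
    if bad.size:
        raise ValueError(f"sample times outside the query curve span [{lo}, {hi}]: {bad.tolist()}")
    q_idx = np.interp(ts, query.times, np.arange(query.times.size))
    j_to_i = path.query_to_ref(query.times.size)
    ref_idx = np.interp(q_idx, np.arange(j_to_i.size), j_to_i)
    mapped = np.interp(ref_idx, np.arange(ref.times.size), ref.times)
    label = dataset_label or query.dataset_label
    # the reference dataset's samples map identically and need no entry
    return UnifiedTimeline(
        reference_label=ref.dataset_label,
        datasets={label: {"original_times": ts, "mapped_times": mapped}},
    )


def merge_metabolome(lcms: OmicsMatrix, gctof: OmicsMatrix) -> OmicsMatrix:
    """Merge two metabolome platforms onto the LC-MS sampling grid.

    GC-TOFMS rows are linearly interpolated at the LC-MS sample times (both
    on the unified timeline) and row-stacked below the LC-MS rows. Times
    outside the GC-TOFMS span clamp to the endpoint value with a warning;
    metabolites measured on both platforms keep the LC-MS row.
    """
    t_target = lcms.sample_times
    t_src = gctof.sample_times
    if t_target.min() < t_src.min() - 1e-9 or t_target.max() > t_src.max() + 1e-9:
        warnings.warn("LC-MS time outside GC-TOFMS span; endpoint values used")
    dup = sorted(set(lcms.molecule_ids) & set(gctof.molecule_ids))
    if dup:
        warnings.warn(f"{len(dup)} metabolites on both platforms; LC-MS rows kept: {dup[:5]}")
    keep = [i for i, mid in enumerate(gctof.molecule_ids) if mid not in set(dup)]
    interp = np.vstack([np.interp(t_target, t_src, gctof.values[i]) for i in keep])
    prov = dict(lcms.provenance)
    prov["merged_from"] = [lcms.omics_label, gctof.omics_label]
    return OmicsMatrix(
        values=np.vstack([lcms.values, interp]),
        molecule_ids=list(lcms.molecule_ids) + [gctof.molecule_ids[i] for i in keep],
        sample_ids=list(lcms.sample_ids),
        sample_times=t_target.copy(),
        omics_label="metabolome",
        provenance=prov,
    )
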