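"""SVD stratification and dual eigen-analysis of omics matrices.

A signal matrix A (molecules x samples) is stratified into ranked
eigen-components ("levels") A = sum_k lambda_k u_k v_k^T. After
normalization the level with the largest singular value is a baseline: its
sample loadings are nearly equal, v_0 ~ (1/sqrt(n)) 1, so
lambda_0 u_0 v_0^T ~ mu 1^T with mu the per-molecule mean. The remaining
levels carry the cyclic variance; levels 1 and 2 define the four
eigen-phases 1A/1B/2A/2B from the signs of their sample loadings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix

__all__ = [
    "EigenLevel",
    "EigenDecomposition",
    "LevelContributions",
    "PhaseCalls",
    "stratify",
    "baseline_diagnostics",
    "remove_baseline",
    "relative_contributions",
    "polarize",
    "call_phases",
    "reconstruct",
    "concat_prepare",
    "concat_and_stratify",
    "orient_to_reference",
]

RANK_RTOL = 1e-10  # singular values below RANK_RTOL * lambda_0 are discarded
BOUNDARY_TOL = 1e-12  # |loading| below this is a sign boundary
CONTRAST_TOL = 0.15  # empirical-contrast check |sum_j v_kj| for k >= 1


@dataclass
class EigenLevel:
    """One eigen-component: singular value and its paired eigenvectors."""

    index: int
    singular_value: float
    molecule_loadings: np.ndarray
    sample_loadings: np.ndarray
    orientation_flag: int = 1


@dataclass
class EigenDecomposition:
    """Ranked eigen-levels of one (possibly concatenated) omics matrix.

    ``index_offset`` is 0 for a plain decomposition (level 0 = baseline) and
    1 for a concatenated decomposition whose baseline was removed before SVD.
    ``segments`` maps dataset labels to column slices for concatenations.
    """

    lambdas: np.ndarray  # (s,) positive, non-increasing
    U: np.ndarray  # (m, s) orthonormal columns, molecule loadings
    V: np.ndarray  # (n, s) orthonormal columns, sample loadings
    molecule_ids: list[str]
    sample_ids: list[str]
    sample_times: np.ndarray
    source_values: np.ndarray  # the matrix that was decomposed
    source_labels: list[str]
    orientation_flags: np.ndarray = None
    index_offset: int = 0
    segments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.orientation_flags is None:
            self.orientation_flags = np.ones(self.lambdas.size, dtype=int)
        if np.any(self.lambdas <= 0) or np.any(np.diff(self.lambdas) > 0):
            raise ValueError("singular values must be positive and non-increasing")

    @property
    def s(self) -> int:
        """Number of retained levels (positive singular values)."""
        return int(self.lambdas.size)

    @property
    def level_indices(self) -> list[int]:
        return [k + self.index_offset for k in range(self.s)]

    def _pos(self, k: int) -> int:
        pos = k - self.index_offset
        if not 0 <= pos < self.s:
            raise IndexError(f"no level {k} (valid: {self.level_indices})")
        return pos

    def level(self, k: int) -> EigenLevel:
        pos = self._pos(k)
        return EigenLevel(
            index=k,
            singular_value=float(self.lambdas[pos]),
            molecule_loadings=self.U[:, pos],
            sample_loadings=self.V[:, pos],
            orientation_flag=int(self.orientation_flags[pos]),
        )

    @property
    def levels(self) -> list[EigenLevel]:
        return [self.level(k) for k in self.level_indices]

    def flip_level(self, k: int) -> None:
        """Negate both eigenvectors of level k (an equivalent SVD)."""
        pos = self._pos(k)
        self.U[:, pos] = -self.U[:, pos]
        self.V[:, pos] = -self.V[:, pos]
        self.orientation_flags[pos] = -self.orientation_flags[pos]

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"k": self.level_indices, "lambda": self.lambdas}).to_csv(
            path / "levels.tsv", sep="\t", index=False
        )
        for k in self.level_indices:
            lev = self.level(k)
            pd.DataFrame({"molecule_id": self.molecule_ids, "loading": lev.molecule_loadings}).to_csv(
                path / f"u_{k}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {
                    "sample_id": self.sample_ids,
                    "time_h": self.sample_times,
                    "loading": lev.sample_loadings,
                }
            ).to_csv(path / f"v_{k}.tsv", sep="\t", index=False)
        meta = {
            "source_labels": self.source_labels,
            "index_offset": self.index_offset,
            "orientation_flags": [int(f) for f in self.orientation_flags],
            "segments": {lab: [int(a), int(b)] for lab, (a, b) in self.segments.items()},
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(self.source_values, index=self.molecule_ids, columns=self.sample_ids).rename_axis(
            "molecule_id"
        ).to_csv(path / "source_matrix.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path) -> "EigenDecomposition":
        path = Path(path)
        levels = pd.read_csv(path / "levels.tsv", sep="\t")
        meta = json.loads((path / "meta.json").read_text())
        ks = levels["k"].tolist()
        U, V = [], []
        times = samples = molecules = None
        for k in ks:
            u = pd.read_csv(path / f"u_{k}.tsv", sep="\t")
            v = pd.read_csv(path / f"v_{k}.tsv", sep="\t")
            U.append(u["loading"].to_numpy())
            V.append(v["loading"].to_numpy())
            molecules = [str(x) for x in u["molecule_id"]]
            samples = [str(x) for x in v["sample_id"]]
            times = v["time_h"].to_numpy(dtype=float)
        src = pd.read_csv(path / "source_matrix.tsv", sep="\t", index_col=0)
        return cls(
            lambdas=levels["lambda"].to_numpy(dtype=float),
            U=np.column_stack(U),
            V=np.column_stack(V),
            molecule_ids=molecules,
            sample_ids=samples,
            sample_times=times,
            source_values=src.to_numpy(dtype=float),
            source_labels=list(meta["source_labels"]),
            orientation_flags=np.array(meta["orientation_flags"], dtype=int),
            index_offset=int(meta["index_offset"]),
            segments={lab: tuple(ab) for lab, ab in meta.get("segments", {}).items()},
        )


@dataclass
class LevelContributions:
    """Relative variance contributions of the non-baseline levels."""

    level_indices: list[int]
    ratios: np.ndarray  # p_k, sum to 1
    eigen_entropy: float  # H = -sum p ln p, nats
    normalized_entropy: float | None  # H / ln(number of levels), if > 1 level

    def top_two(self) -> float:
        """Combined contribution of the first two non-baseline levels."""
        return float(np.sum(self.ratios[:2]))


@dataclass
class PhaseCalls:
    """Per-sample eigen-phase labels from loading signs at levels 1 and 2."""

    table: pd.DataFrame  # sample_id, time_h, sign1, sign2, label1, label2, boundary
    cyclic_order: list[str]  # the four labels in cycle traversal order
    duplicate_midpoints: bool = False
    rotation_ambiguous: bool = False


def _orient_levels(lambdas: np.ndarray, U: np.ndarray, V: np.ndarray, baseline: bool) -> np.ndarray:
    """Deterministic sign fix. Baseline level: sum of sample loadings >= 0.
    Other levels: skewness of molecule loadings >= 0; if skewness is
    numerically zero, the largest-|loading| molecule is made positive."""
    flags = np.ones(lambdas.size, dtype=int)
    for pos in range(lambdas.size):
        if baseline and pos == 0:
            flip = np.sum(V[:, 0]) < 0
        else:
            sk = stats.skew(U[:, pos])
            if abs(sk) < 1e-12:
                flip = U[np.argmax(np.abs(U[:, pos])), pos] < 0
            else:
                flip = sk < 0
        if flip:
            U[:, pos] = -U[:, pos]
            V[:, pos] = -V[:, pos]
            flags[pos] = -1
    return flags


def stratify(mat: OmicsMatrix) -> EigenDecomposition:
    """Full SVD of the signal matrix into ranked eigen-levels.

    Singular values below ``RANK_RTOL * lambda_0`` are discarded. Signs are
    fixed deterministically (see :func:`_orient_levels`); an empirical-contrast
    warning is emitted when a non-baseline sample-eigenvector has
    ``|sum_j v_kj| > CONTRAST_TOL``.
    """
    A = mat.values
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries")
    Um, lam, Vt = np.linalg.svd(A, full_matrices=False)
    keep = lam > RANK_RTOL * lam[0]
    lam, Um, V = lam[keep], Um[:, keep], Vt[keep].T
    flags = _orient_levels(lam, Um, V, baseline=True)
    sums = np.abs(V[:, 1:].sum(axis=0))
    if np.any(sums > CONTRAST_TOL):
        bad = [k + 1 for k in np.flatnonzero(sums > CONTRAST_TOL)]
        warnings.warn(f"sample-eigenvector contrast check failed at levels {bad}")
    return EigenDecomposition(
        lambdas=lam,
        U=Um,
        V=V,
        molecule_ids=list(mat.molecule_ids),
        sample_ids=list(mat.sample_ids),
        sample_times=mat.sample_times.copy(),
        source_values=A.copy(),
        source_labels=[mat.omics_label],
        orientation_flags=flags,
    )


def baseline_diagnostics(dec: EigenDecomposition, cv_max: float = 0.1) -> dict:
    """Check that level 0 is a clean baseline.

    Reports the coefficient of variation of |v_0|, the maximum relative
    deviation of lambda_0 u_0 / sqrt(n) from the row-mean vector mu, and a
    pass flag (CV <= cv_max). A failed flag warns that level 0 does not
    represent the average matrix.
    """
    if dec.index_offset != 0:
        raise ValueError("decomposition has no baseline level")
    v0 = np.abs(dec.V[:, 0])
    mean = v0.mean()
    cv = float(v0.std(ddof=1) / mean) if mean > 0 else np.inf
    n = dec.V.shape[0]
    mu = dec.source_values.mean(axis=1)
    est = dec.lambdas[0] * dec.U[:, 0] / np.sqrt(n)
    denom = np.max(np.abs(mu))
    mu_dev = float(np.max(np.abs(est - mu)) / denom) if denom > 1e-12 else np.inf
    passed = cv <= cv_max
    if not passed:
        warnings.warn(
            f"level 0 is not a clean baseline (CV of |v_0| = {cv:.3g} > {cv_max}); "
            "baseline removal may not equal mean-centering"
        )
    return {"cv_abs_v0": cv, "mu_max_rel_dev": mu_dev, "passed": passed}


def remove_baseline(dec: EigenDecomposition) -> np.ndarray:
    """A - lambda_0 u_0 v_0^T, the matrix carrying the variance beyond baseline."""
    if dec.index_offset != 0:
        raise ValueError("baseline already removed")
    return dec.source_values - dec.lambdas[0] * np.outer(dec.U[:, 0], dec.V[:, 0])


def relative_contributions(dec: EigenDecomposition) -> LevelContributions:
    """Ratios p_k = lambda_k^2 / sum lambda^2 over non-baseline levels, and
    the eigen-entropy H = -sum p_k ln p_k (nats) of that distribution."""
    start = 1 - dec.index_offset
    lam = dec.lambdas[start:]
    if lam.size == 0:
        raise ValueError("no variance beyond baseline")
    sq = lam**2
    p = sq / sq.sum()
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    norm = float(H / np.log(p.size)) if p.size > 1 else None
    return LevelContributions(
        level_indices=dec.level_indices[start:],
        ratios=p,
        eigen_entropy=H,
        normalized_entropy=norm,
    )


def polarize(level: EigenLevel, molecule_ids=None, sample_ids=None) -> dict[str, pd.DataFrame]:
    """Sort the loadings of a level ascending, tagging poles by sign."""

    def _table(ids, loadings):
        ids = list(ids) if ids is not None else [str(i) for i in range(len(loadings))]
        df = pd.DataFrame({"id": ids, "loading": loadings})
        df = df.sort_values("loading", kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(len(df))
        df["pole"] = np.where(df["loading"] < 0, "negative", "positive")
        return df

    return {
        "molecules": _table(molecule_ids, level.molecule_loadings),
        "samples": _table(sample_ids, level.sample_loadings),
    }


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def call_phases(dec: EigenDecomposition, a_positive: bool = True) -> PhaseCalls:
    """Assign the four eigen-phase labels from the signs of v_1 and v_2.

    Each sample gets one level-1 label (1A/1B) and one level-2 label (2A/2B);
    by default A marks the positive pole. The cyclic order of the four labels
    is inferred from the circular sequence of label midpoints: each sample's
    position in the cycle is the angle atan2(v_2j, v_1j), the traversal
    direction is the sign of the summed wrapped angle increments over
    time-ordered samples, and the reported order starts at 1B.

    Samples with |loading| < BOUNDARY_TOL at either level are flagged
    "boundary" and excluded from order inference.
    """
    lo = dec.index_offset
    if max(dec.level_indices) < 2:
        raise ValueError("need at least levels 1 and 2 beyond baseline")
    v1 = dec.level(1).sample_loadings
    v2 = dec.level(2).sample_loadings
    if abs(dec.level(1).singular_value - dec.level(2).singular_value) < 1e-12 * dec.lambdas[0]:
        warnings.warn("lambda_1 = lambda_2: levels 1 and 2 are rotation-ambiguous")
        rotation_ambiguous = True
    else:
        rotation_ambiguous = False

    pos_label = {1: "1A" if a_positive else "1B", 2: "2A" if a_positive else "2B"}
    neg_label = {1: "1B" if a_positive else "1A", 2: "2B" if a_positive else "2A"}
    boundary = (np.abs(v1) < BOUNDARY_TOL) | (np.abs(v2) < BOUNDARY_TOL)
    label1 = np.where(v1 > 0, pos_label[1], neg_label[1])
    label2 = np.where(v2 > 0, pos_label[2], neg_label[2])
    table = pd.DataFrame(
        {
            "sample_id": dec.sample_ids,
            "time_h": dec.sample_times,
            "sign1": np.sign(v1).astype(int),
            "sign2": np.sign(v2).astype(int),
            "label1": label1,
            "label2": label2,
            "boundary": boundary,
        }
    )

    ok = ~boundary
    theta = np.arctan2(v2[ok], v1[ok])
    order_t = np.argsort(dec.sample_times[ok], kind="stable")
    dtheta = np.diff(theta[order_t])
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    direction = 1.0 if dtheta.sum() >= 0 else -1.0

    membership = {
        pos_label[1]: v1[ok] > 0,
        neg_label[1]: v1[ok] < 0,
        pos_label[2]: v2[ok] > 0,
        neg_label[2]: v2[ok] < 0,
    }
    midpoints = {}
    for lab, mask in membership.items():
        midpoints[lab] = _circular_mean(theta[mask]) if mask.any() else np.nan
    present = [lab for lab, a in midpoints.items() if np.isfinite(a)]
    # traverse in the direction the cycle advances with time; ties by label name
    key = sorted(present, key=lambda lab: (direction * midpoints[lab], lab))
    angles = np.array([midpoints[lab] for lab in present])
    dup = False
    if len(present) > 1:
        diffs = np.abs((angles[:, None] - angles[None, :] + np.pi) % (2 * np.pi) - np.pi)
        dup = bool(np.any(diffs[np.triu_indices(len(present), 1)] < 1e-9))
        if dup:
            warnings.warn("duplicated phase midpoints; cyclic order is partially arbitrary")
    if "1B" in key:
        i = key.index("1B")
        key = key[i:] + key[:i]
    return PhaseCalls(
        table=table,
        cyclic_order=key,
        duplicate_midpoints=dup,
        rotation_ambiguous=rotation_ambiguous,
    )


def reconstruct(dec: EigenDecomposition, keep_levels) -> tuple[np.ndarray, np.ndarray]:
    """Partial reconstruction sum_{k in keep} lambda_k u_k v_k^T and its residual.

    With keep = {0, 1, 2} this realizes the cyclic-signal decomposition
    a(i, t_j) = mu(i) + lambda_1 u_1(i) v_1(t_j) + lambda_2 u_2(i) v_2(t_j)
    + eps(i, t_j).
    """
    keep = sorted(set(int(k) for k in keep_levels))
    positions = [dec._pos(k) for k in keep]  # raises on invalid index
    A = dec.source_values
    if positions:
        approx = (dec.U[:, positions] * dec.lambdas[positions]) @ dec.V[:, positions].T
    else:
        approx = np.zeros_like(A)
    return approx, A - approx


def concat_prepare(mat: OmicsMatrix) -> OmicsMatrix:
    """Prepare a matrix for concatenation: remove the baseline eigen-matrix,
    rescale to unit Frobenius norm, then divide by sqrt(sample count)."""
    dec = stratify(mat)
    Abar = remove_baseline(dec)
    norm = np.linalg.norm(Abar)
    if norm < 1e-12 * np.linalg.norm(mat.values):
        raise ValueError("pure baseline matrix: nothing to concatenate")
    prepared = Abar / norm / np.sqrt(mat.n)
    prov = dict(mat.provenance)
    prov["concat_prepared"] = True
    return OmicsMatrix(
        values=prepared,
        molecule_ids=list(mat.molecule_ids),
        sample_ids=list(mat.sample_ids),
        sample_times=mat.sample_times.copy(),
        omics_label=mat.omics_label,
        provenance=prov,
    )


def concat_and_stratify(m1: OmicsMatrix, m2: OmicsMatrix) -> EigenDecomposition:
    """Column-concatenate two prepared matrices on common molecules and SVD.

    Level indexing starts at 1, reflecting the prior removal of baselines.
    Each sample-eigenvector can be partitioned back into per-dataset segments
    via ``segments``.
    """
    if m1.molecule_ids != m2.molecule_ids:
        only1 = sorted(set(m1.molecule_ids) - set(m2.molecule_ids))
        only2 = sorted(set(m2.molecule_ids) - set(m1.molecule_ids))
        if only1 or only2:
            raise ValueError(
                f"molecule mismatch: {len(only1)} only in first (e.g. {only1[:5]}), "
                f"{len(only2)} only in second (e.g. {only2[:5]})"
            )
        raise ValueError("molecule ids must be in the same order; reindex first")
    A = np.hstack([m1.values, m2.values])
    Um, lam, Vt = np.linalg.svd(A, full_matrices=False)
    keep = lam > RANK_RTOL * lam[0]
    lam, Um, V = lam[keep], Um[:, keep], Vt[keep].T
    flags = _orient_levels(lam, Um, V, baseline=False)
    sample_ids = [f"{m1.omics_label}:{s}" for s in m1.sample_ids] + [
        f"{m2.omics_label}:{s}" for s in m2.sample_ids
    ]
    times = np.concatenate([m1.sample_times, m2.sample_times])
    return EigenDecomposition(
        lambdas=lam,
        U=Um,
        V=V,
        molecule_ids=list(m1.molecule_ids),
        sample_ids=sample_ids,
        sample_times=times,
        source_values=A,
        source_labels=[m1.omics_label, m2.omics_label],
        orientation_flags=flags,
        index_offset=1,
        segments={m1.omics_label: (0, m1.n), m2.omics_label: (m1.n, m1.n + m2.n)},
    )


def orient_to_reference(dec: EigenDecomposition, k: int, reference_loadings: np.ndarray) -> None:
    """Flip level k in place so its sample loadings correlate positively with
    a reference series (e.g. a planted periodic function or another dataset's
    matched level). Resolves the inherent SVD sign ambiguity."""
    v = dec.level(k).sample_loadings
    if float(np.dot(v, reference_loadings)) < 0:
        dec.flip_level(k)
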