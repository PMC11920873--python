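"""Interpretation of molecule-eigenvectors.

Three tools link eigen-levels back to biology:

* rank-sum gene-set enrichment of a level's molecule loadings, per pole;
* marker-molecule significance by randomizing the sample-eigenvector in the
  orthogonal complement of the leading levels (using lambda_k u_k = A v_k);
* phase-contribution decomposition of an auxiliary signal matrix (e.g. a
  histone modification) under the nonnegative parts of a reference
  decomposition's eigenvectors, with the CV across the four phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .eigen import EigenDecomposition
from .io import OmicsMatrix

__all__ = [
    "wilcoxon_enrich",
    "random_orthogonal_vector",
    "marker_randomization",
    "phase_contributions",
    "MarkerResult",
]

EXACT_MAX_TOTAL = 25  # exact rank-sum distribution below this problem size
EXACT_MAX_SET = 10


@dataclass
class MarkerResult:
    molecule_id: str
    level: int
    loading: float
    p_value: float
    is_marker: bool


def _ranksum_pvalues(in_set: np.ndarray, out_set: np.ndarray) -> tuple[float, float, float]:
    """Signed z and one-sided p-values (greater, less) for in-set loadings.

    Uses the exact rank-sum distribution for small tie-free problems and the
    continuity-corrected normal approximation (with tie correction) otherwise.
    """
    n1, n2 = in_set.size, out_set.size
    pooled = np.concatenate([in_set, out_set])
    ties = np.unique(pooled).size < pooled.size
    small = n1 <= EXACT_MAX_SET and (n1 + n2) <= EXACT_MAX_TOTAL and not ties
    method = "exact" if small else "asymptotic"
    res_g = stats.mannwhitneyu(in_set, out_set, alternative="greater", method=method)
    res_l = stats.mannwhitneyu(in_set, out_set, alternative="less", method=method)
    mu = n1 * n2 / 2.0
    tie_term = 0.0
    if ties:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    sd = np.sqrt(n1 * n2 / 12.0 * (n1 + n2 + 1.0 - tie_term))
    z = (res_g.statistic - mu) / sd if sd > 0 else 0.0
    return float(z), float(res_g.pvalue), float(res_l.pvalue)


def wilcoxon_enrich(
    loadings: pd.Series,
    gene_sets: dict[str, list[str]],
    min_size: int = 5,
) -> pd.DataFrame:
    """Rank-sum scoring of gene sets against a molecule-loading vector.

    Loadings play the role of a weighted differential profile: sets shifted
    toward high loadings are enriched at the positive pole and vice versa.
    Each set with at least ``min_size`` members in the matrix is tested
    in-set vs out-of-set; one-sided p-values are reported per pole with a
    signed z, and BH adjustment runs within each pole across all tested sets.
    """
    ids = pd.Index(loadings.index)
    values = loadings.to_numpy(dtype=float)
    rows = []
    for name, members in gene_sets.items():
        mask = ids.isin(set(members))
        size = int(mask.sum())
        if size < min_size:
            continue
        if size == ids.size:
            # empty complement: degenerate test
            rows.append({"set_id": name, "set_size": size, "z": 0.0, "p_pos": 1.0, "p_neg": 1.0})
            continue
        z, p_pos, p_neg = _ranksum_pvalues(values[mask], values[~mask])
        rows.append({"set_id": name, "set_size": size, "z": z, "p_pos": p_pos, "p_neg": p_neg})
    if not rows:
        warnings.warn(f"no gene set with >= {min_size} members in the matrix")
        return pd.DataFrame(
            columns=["set_id", "set_size", "direction", "z", "p", "q"]
        )
    df = pd.DataFrame(rows)
    out = []
    for direction, col in (("positive", "p_pos"), ("negative", "p_neg")):
        part = df[["set_id", "set_size", "z"]].copy()
        part["direction"] = direction
        part["p"] = df[col]
        part["q"] = multipletests(part["p"].to_numpy(), method="fdr_bh")[1]
        out.append(part)
    return (
        pd.concat(out, ignore_index=True)[["set_id", "set_size", "direction", "z", "p", "q"]]
        .sort_values(["direction", "p"], kind="stable")
        .reset_index(drop=True)
    )


def random_orthogonal_vector(
    dec: EigenDecomposition, k: int, rng: np.random.Generator
) -> np.ndarray:
    """A random unit sample-vector orthogonal to v_0 .. v_k.

    Standard-normal draw, sequentially projected out of the leading
    sample-eigenvectors, then normalized; redrawn in the (measure-zero)
    event the residual norm is below 1e-8.
    """
    top = k - dec.index_offset + 1  # positions of v_0..v_k in V
    n = dec.V.shape[0]
    if top >= n:
        raise ValueError(f"no orthogonal complement beyond level {k} with n = {n}")
    basis = dec.V[:, :top]
    for _ in range(100):
        x = rng.standard_normal(n)
        x = x - basis @ (basis.T @ x)
        norm = np.linalg.norm(x)
        if norm >= 1e-8:
            return x / norm
    raise RuntimeError("failed to draw a vector in the orthogonal complement")


def marker_randomization(
    mat: OmicsMatrix,
    dec: EigenDecomposition,
    k: int,
    R: int = 1000,
    seed: int | None = None,
    p_max: float = 0.01,
    u_min: float | None = None,
) -> list[MarkerResult]:
    """Per-molecule significance of loadings at level k by randomization.

    Random sample-eigenvectors v_k^r (unit norm, orthogonal to v_0..v_k) are
    pushed through the data, u_k^r = A v_k^r / ||A v_k^r||, forming a null
    for each molecule's loading. The tail is selected by the observed sign
    (upper for positive loadings, lower for negative; exactly-zero loadings
    get p = 1) and counted with the +1 finite-sample correction; because the
    tail is chosen after seeing the sign, the selected-tail probability is
    doubled to keep the p-value valid (uniform under an isotropic null):
    p = min(1, 2 (1 + count) / (1 + R)).

    Markers satisfy p <= p_max and |loading| >= u_min (default: the 95th
    percentile of |loadings| at this level).
    """
    if R < 100:
        raise ValueError("R must be >= 100")
    rng = np.random.default_rng(seed)
    A = mat.values
    u_obs = dec.level(k).molecule_loadings
    if u_min is None:
        u_min = float(np.percentile(np.abs(u_obs), 95))
    null = np.empty((A.shape[0], R))
    redraws = 0
    for r in range(R):
        for _ in range(100):
            v = random_orthogonal_vector(dec, k, rng)
            u = A @ v
            norm = np.linalg.norm(u)
            if norm >= 1e-12:
                break
            redraws += 1
        else:
            raise RuntimeError("A maps the whole orthogonal complement to ~0")
        null[:, r] = u / norm
    if redraws > 0.01 * R:
        warnings.warn(f"{redraws} degenerate randomization draws were redone")

    ge = (null >= u_obs[:, None]).sum(axis=1)
    le = (null <= u_obs[:, None]).sum(axis=1)
    tail = np.where(u_obs > 0, (1.0 + ge) / (1.0 + R), (1.0 + le) / (1.0 + R))
    p = np.minimum(1.0, 2.0 * tail)
    p = np.where(u_obs == 0, 1.0, p)
    return [
        MarkerResult(
            molecule_id=mol,
            level=k,
            loading=float(u_obs[i]),
            p_value=float(p[i]),
            is_marker=bool(p[i] <= p_max and abs(u_obs[i]) >= u_min),
        )
        for i, mol in enumerate(dec.molecule_ids)
    ]


def _split_normalize(w: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    pos = np.maximum(w, 0.0)
    neg = np.maximum(-w, 0.0)
    if pos.sum() <= 0 or neg.sum() <= 0:
        raise ValueError(f"{name} is one-signed: cannot form both phase weight vectors")
    return pos / pos.sum(), neg / neg.sum()


def phase_contributions(
    signal: OmicsMatrix,
    tdec: EigenDecomposition,
    transcript_times: np.ndarray | None = None,
) -> dict:
    """Contribution of an auxiliary signal matrix to the four eigen-phases.

    The reference (transcriptome) eigenvectors at levels 1 and 2 are split
    into nonnegative parts normalized to sum 1; the signal matrix, linearly
    interpolated per gene to the transcriptomic sampling times, is then
    weighted as c(1A) = u1+^T A v1+, c(1B) = u1-^T A v1-, c(2A) = u2+^T A v2+,
    c(2B) = u2-^T A v2-. The CV (sample sd / mean) over the four
    contributions measures how phase-specific the signal is.
    """
    if transcript_times is None:
        transcript_times = tdec.sample_times
    transcript_times = np.asarray(transcript_times, dtype=float)

    common = [mid for mid in tdec.molecule_ids if mid in set(signal.molecule_ids)]
    if len(common) < 2:
        raise ValueError("fewer than 2 molecules shared with the reference decomposition")
    if len(common) < len(tdec.molecule_ids):
        warnings.warn(
            f"{len(tdec.molecule_ids) - len(common)} reference molecules missing from signal matrix"
        )
    sig_pos = {mid: i for i, mid in enumerate(signal.molecule_ids)}
    ref_pos = {mid: i for i, mid in enumerate(tdec.molecule_ids)}
    rows = [sig_pos[mid] for mid in common]
    A = np.vstack(
        [np.interp(transcript_times, signal.sample_times, signal.values[i]) for i in rows]
    )

    idx = [ref_pos[mid] for mid in common]
    u1 = tdec.level(1).molecule_loadings[idx]
    u2 = tdec.level(2).molecule_loadings[idx]
    v1 = tdec.level(1).sample_loadings
    v2 = tdec.level(2).sample_loadings
    u1p, u1n = _split_normalize(u1, "u_1")
    u2p, u2n = _split_normalize(u2, "u_2")
    v1p, v1n = _split_normalize(v1, "v_1")
    v2p, v2n = _split_normalize(v2, "v_2")

    contributions = {
        "1A": float(u1p @ A @ v1p),
        "1B": float(u1n @ A @ v1n),
        "2A": float(u2p @ A @ v2p),
        "2B": float(u2n @ A @ v2n),
    }
    vals = np.array(list(contributions.values()))
    mean = vals.mean()
    cv = float(vals.std(ddof=1) / mean) if mean != 0 else np.inf
    return {
        "label": signal.omics_label,
        "contributions": contributions,
        "cv": cv,
        "n_molecules": len(common),
    }
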