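"""Behavioral partial least squares on score-activation correlation maps.

The analysis stacks, for every (group, condition) cell, the Pearson
correlation across that group's subjects between a polygenic score and each
voxel's activation, into a cells x voxels matrix R. The SVD of R yields
latent variables (LVs): a behavior-side salience vector over cells, a
unit-norm voxel-side salience vector, and a singular value whose squared
share of the total is the percent crossblock covariance.

Inference follows the standard task-PLS recipe: LV significance by
permuting the score-to-subject assignment within each group (the null of no
score-brain association) and comparing singular values; voxel reliability by
bootstrap resampling subjects within group, aligning each bootstrap solution
to the original by orthogonal Procrustes on the behavior saliences, and
forming bootstrap ratios (BSR = original salience / bootstrap SD). Reliable
voxels (|BSR| above threshold) are reported as sign-specific connected
components on the voxel grid above a minimum cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.linalg import orthogonal_procrustes
from sklearn.base import BaseEstimator

from ._utils import rng_for, zscore_columns
from .simulate import ActivationData

logger = logging.getLogger(__name__)


@dataclass
class PLSResult:
    rows: list  # ordered (group, condition) cells
    R: np.ndarray
    singular_values: np.ndarray
    behavior_saliences: np.ndarray  # rows x n_lv
    voxel_saliences: np.ndarray  # voxels x n_lv, unit columns
    pct_crossblock: np.ndarray
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None
    behavior_ci: dict | None = None  # (cell, lv) -> (lo, hi)
    brainscores: dict | None = None  # condition -> subjects x n_lv
    clusters: pd.DataFrame | None = None

    def __post_init__(self):
        s = self.singular_values
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("singular values must be sorted descending")
        if abs(self.pct_crossblock.sum() - 100.0) > 1e-6:
            raise ValueError("pct_crossblock must sum to 100")


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def _cells(act: ActivationData) -> list:
    groups = list(pd.unique(act.group))
    return [(g, c) for g in groups for c in act.conditions]


def _group_indices(act: ActivationData) -> dict:
    grp = act.group.to_numpy()
    return {g: np.flatnonzero(grp == g) for g in pd.unique(grp)}


def build_correlation_matrix(
    act: ActivationData, score, rows: list | None = None
) -> tuple[np.ndarray, list]:
    """Cells x voxels Pearson correlation matrix between score and activation.

    Zero-variance voxels within a cell get correlation 0 (logged). Returns
    (R, ordered cell list).
    """
    score = pd.Series(score).loc[list(act.subject_ids)]
    if score.isna().any():
        raise ValueError("score must be defined for every subject")
    rows = rows or _cells(act)
    gidx = _group_indices(act)
    for g, n in ((g, len(ix)) for g, ix in gidx.items()):
        if n < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    s = score.to_numpy(float)
    R = np.zeros((len(rows), act.n_voxels))
    n_constant = 0
    for r_i, (g, c) in enumerate(rows):
        ix = gidx[g]
        sz = s[ix]
        sd = sz.std()
        if sd == 0:
            raise ValueError(f"score is constant within group {g!r}")
        sz = (sz - sz.mean()) / sd
        z, constant = zscore_columns(act.matrices[c][ix])
        n_constant += int(constant.sum())
        R[r_i] = sz @ z / len(ix)
    if n_constant:
        logger.warning("%d zero-variance voxel cells set to correlation 0", n_constant)
    return R, rows


# ---------------------------------------------------------------------------
# SVD
# ---------------------------------------------------------------------------

def pls_svd(R: np.ndarray, rows: list | None = None) -> PLSResult:
    """SVD of the correlation matrix with a deterministic sign convention
    (each voxel-salience column's largest-magnitude entry is positive)."""
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValueError("R must be finite")
    if np.all(R == 0):
        raise ValueError("R is identically zero")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    pct = 100.0 * s**2 / np.sum(s**2)
    return PLSResult(
        rows=rows or [("cell", i) for i in range(R.shape[0])],
        R=R,
        singular_values=s,
        behavior_saliences=U,
        voxel_saliences=V,
        pct_crossblock=pct,
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    act: ActivationData, score, n_perm: int = 500, seed=None,
    observed: PLSResult | None = None,
) -> np.ndarray:
    """Permutation p per LV: shuffle score-to-subject assignment within each
    group, rebuild R, take singular values; p_k = (1 + #{s_perm >= s_obs}) /
    (1 + n_perm)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng_for(seed, 101)
    score = pd.Series(score).loc[list(act.subject_ids)]
    res = observed or pls_svd(*build_correlation_matrix(act, score))
    gidx = _group_indices(act)
    s = score.to_numpy(float)

    # pre-standardize activations per cell so each permutation is two matmuls
    zact = {}
    zs = {}
    for g, ix in gidx.items():
        sz = s[ix]
        zs[g] = (sz - sz.mean()) / sz.std()
        for c in act.conditions:
            zact[(g, c)], _ = zscore_columns(act.matrices[c][ix])

    rows = res.rows
    counts = np.zeros(len(res.singular_values))
    for _ in range(n_perm):
        Rp = np.zeros_like(res.R)
        perm = {g: rng.permutation(zs[g]) for g in gidx}
        for r_i, (g, c) in enumerate(rows):
            Rp[r_i] = perm[g] @ zact[(g, c)] / len(gidx[g])
        sp = np.linalg.svd(Rp, compute_uv=False)
        counts += sp >= res.singular_values
    return (1.0 + counts) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_saliences(
    act: ActivationData, score, n_boot: int = 1000, seed=None,
    observed: PLSResult | None = None, max_redraw: int = 100,
) -> tuple[np.ndarray, dict]:
    """Bootstrap ratios and behavior-side confidence intervals.

    Subjects are resampled with replacement within group; each bootstrap
    solution is aligned to the original by orthogonal Procrustes on the
    behavior saliences. Following the usual PLS convention the bootstrap
    operates on singular-value-scaled voxel saliences (V S), so singular-value
    variability propagates into the standard error:
    BSR(v, k) = v_k(v) s_k / SD_boot(scaled salience). behavior_ci maps
    (cell, lv) to the 2.5/97.5 percentiles of the bootstrapped within-cell
    correlation between score and brainscore.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng_for(seed, 202)
    score = pd.Series(score).loc[list(act.subject_ids)]
    res = observed or pls_svd(*build_correlation_matrix(act, score))
    gidx = _group_indices(act)
    s = score.to_numpy(float)
    rows = res.rows
    K = res.voxel_saliences.shape[1]

    V_samples = np.empty((n_boot, act.n_voxels, K))
    corr_samples = np.empty((n_boot, len(rows), K))
    for b in range(n_boot):
        for _attempt in range(max_redraw):
            draw = {g: rng.choice(ix, size=len(ix), replace=True) for g, ix in gidx.items()}
            if all(len(np.unique(ix)) >= 3 and s[ix].std() > 0 for ix in draw.values()):
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        Rb = np.zeros_like(res.R)
        zs_b, zact_b = {}, {}
        for g, ix in draw.items():
            sz = s[ix]
            zs_b[g] = (sz - sz.mean()) / sz.std()
        for r_i, (g, c) in enumerate(rows):
            z, _ = zscore_columns(act.matrices[c][draw[g]])
            zact_b[(g, c)] = z
            Rb[r_i] = zs_b[g] @ z / len(draw[g])
        Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        Q, _ = orthogonal_procrustes(Ub, res.behavior_saliences)
        Vb = Vbt.T @ Q  # unit saliences, for brainscore projections
        V_samples[b] = ((Vbt.T * sb) @ Q)[:, :K]  # scaled saliences
        for r_i, (g, c) in enumerate(rows):
            proj = zact_b[(g, c)] @ Vb[:, :K]  # n_g x K
            pz, _ = zscore_columns(proj)
            corr_samples[b, r_i] = zs_b[g] @ pz / len(draw[g])

    scaled = res.voxel_saliences * res.singular_values[None, :K]
    sd = V_samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(sd > 0, scaled / sd, np.inf * np.sign(scaled))
    bsr[scaled == 0] = 0.0
    lo = np.percentile(corr_samples, 2.5, axis=0)
    hi = np.percentile(corr_samples, 97.5, axis=0)
    behavior_ci = {
        (rows[r_i], k): (float(lo[r_i, k]), float(hi[r_i, k]))
        for r_i in range(len(rows))
        for k in range(K)
    }
    return bsr, behavior_ci


# ---------------------------------------------------------------------------
# brainscores
# ---------------------------------------------------------------------------

def brainscores(act: ActivationData, voxel_salience: np.ndarray) -> pd.DataFrame:
    """Per-subject, per-condition projection onto one LV's voxel saliences."""
    v = np.asarray(voxel_salience, dtype=float)
    out = {c: act.matrices[c] @ v for c in act.conditions}
    return pd.DataFrame(out, index=list(act.subject_ids))


# ---------------------------------------------------------------------------
# cluster report
# ---------------------------------------------------------------------------

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def cluster_report(
    bsr_column: np.ndarray,
    voxel_table: pd.DataFrame,
    threshold: float = 2.5,
    min_cluster_size: int = 20,
    connectivity: int = 6,
    lv: int = 1,
) -> pd.DataFrame:
    """Sign-specific connected components of suprathreshold (|BSR| > thr)
    voxels on the grid; only components with n_voxels > min_cluster_size are
    reported, sorted by peak |BSR|."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    bsr_column = np.asarray(bsr_column, dtype=float)
    coords = voxel_table[["x", "y", "z"]].to_numpy(int)
    dims = coords.max(axis=0) + 1
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    records = []
    for sign, mask in (
        (1, bsr_column > threshold),
        (-1, bsr_column < -threshold),
    ):
        grid = np.zeros(dims, dtype=bool)
        grid[coords[mask, 0], coords[mask, 1], coords[mask, 2]] = True
        labels, n_lab = ndimage.label(grid, structure=structure)
        if n_lab == 0:
            continue
        voxel_labels = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
        voxel_labels[~mask] = 0
        for lab in range(1, n_lab + 1):
            members = np.flatnonzero(voxel_labels == lab)
            if len(members) <= min_cluster_size:
                continue
            peak = members[np.argmax(np.abs(bsr_column[members]))]
            records.append(
                {
                    "lv": lv,
                    "sign": sign,
                    "n_voxels": len(members),
                    "peak_bsr": float(bsr_column[peak]),
                    "peak_x": int(coords[peak, 0]),
                    "peak_y": int(coords[peak, 1]),
                    "peak_z": int(coords[peak, 2]),
                    "member_voxel_ids": voxel_table["voxel_id"].to_numpy()[members].tolist(),
                }
            )
    df = pd.DataFrame(
        records,
        columns=["lv", "sign", "n_voxels", "peak_bsr", "peak_x", "peak_y",
                 "peak_z", "member_voxel_ids"],
    )
    if len(df):
        df = df.sort_values("peak_bsr", key=np.abs, ascending=False).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class BehavioralPLS(BaseEstimator):
    """Behavioral PLS with permutation and bootstrap inference.

    Parameters mirror the analysis defaults: 500 permutations, 1000
    bootstraps, |BSR| > 2.5 voxel reliability, clusters > 20 voxels under
    6-connectivity.

    After ``fit(activations, score)`` the result lives in ``result_`` (a
    :class:`PLSResult`) and in flat attributes ``singular_values_``,
    ``behavior_saliences_``, ``voxel_saliences_``, ``pct_crossblock_``,
    ``perm_p_``, ``bsr_``, ``behavior_ci_``, ``brainscores_``, ``clusters_``.
    """

    def __init__(
        self,
        n_perm: int = 500,
        n_boot: int = 1000,
        bsr_threshold: float = 2.5,
        min_cluster_size: int = 20,
        connectivity: int = 6,
        n_report_lvs: int = 1,
        random_state=None,
    ):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.bsr_threshold = bsr_threshold
        self.min_cluster_size = min_cluster_size
        self.connectivity = connectivity
        self.n_report_lvs = n_report_lvs
        self.random_state = random_state

    def fit(self, activations: ActivationData, score):
        R, rows = build_correlation_matrix(activations, score)
        res = pls_svd(R, rows)
        res.perm_p = permutation_test(
            activations, score, n_perm=self.n_perm, seed=self.random_state,
            observed=res,
        )
        res.bsr, res.behavior_ci = bootstrap_saliences(
            activations, score, n_boot=self.n_boot, seed=self.random_state,
            observed=res,
        )
        res.brainscores = {
            k: brainscores(activations, res.voxel_saliences[:, k])
            for k in range(min(self.n_report_lvs, res.voxel_saliences.shape[1]))
        }
        tables = [
            cluster_report(
                res.bsr[:, k], activations.voxel_table,
                threshold=self.bsr_threshold,
                min_cluster_size=self.min_cluster_size,
                connectivity=self.connectivity, lv=k + 1,
            )
            for k in range(min(self.n_report_lvs, res.bsr.shape[1]))
        ]
        res.clusters = pd.concat(tables, ignore_index=True) if tables else None
        self.result_ = res
        self.rows_ = res.rows
        self.singular_values_ = res.singular_values
        self.behavior_saliences_ = res.behavior_saliences
        self.voxel_saliences_ = res.voxel_saliences
        self.pct_crossblock_ = res.pct_crossblock
        self.perm_p_ = res.perm_p
        self.bsr_ = res.bsr
        self.behavior_ci_ = res.behavior_ci
        self.brainscores_ = res.brainscores
        self.clusters_ = res.clusters
        return self


def save_pls_result(res: PLSResult, outdir) -> None:
    """Serialize a PLSResult as a directory of TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "lv": np.arange(1, len(res.singular_values) + 1),
            "singular_value": res.singular_values,
            "pct_crossblock": res.pct_crossblock,
            "perm_p": res.perm_p if res.perm_p is not None else np.nan,
        }
    ).to_csv(outdir / "singular_values.tsv", sep="\t", index=False)
    rows = pd.MultiIndex.from_tuples(res.rows, names=["group", "condition"])
    pd.DataFrame(
        res.behavior_saliences, index=rows,
        columns=[f"LV{k + 1}" for k in range(res.behavior_saliences.shape[1])],
    ).to_csv(outdir / "behavior_saliences.tsv", sep="\t")
    pd.DataFrame(
        res.voxel_saliences,
        columns=[f"LV{k + 1}" for k in range(res.voxel_saliences.shape[1])],
    ).to_csv(outdir / "voxel_saliences.tsv", sep="\t", index_label="voxel_index")
    if res.bsr is not None:
        pd.DataFrame(
            res.bsr, columns=[f"LV{k + 1}" for k in range(res.bsr.shape[1])]
        ).to_csv(outdir / "bsr.tsv", sep="\t", index_label="voxel_index")
    if res.brainscores is not None:
        for k, df in res.brainscores.items():
            df.to_csv(outdir / f"brainscores_LV{k + 1}.tsv", sep="\t",
                      index_label="subject_id")
    if res.clusters is not None:
        out = res.clusters.copy()
        if len(out):
            out["member_voxel_ids"] = out["member_voxel_ids"].map(",".join)
        out.to_csv(outdir / "clusters.tsv", sep="\t", index=False)


def export_bsr_nifti(bsr_column, voxel_table, path) -> None:
    """Write one BSR map as NIfTI when the voxels fully tile a box grid."""
    import nibabel as nib

    coords = voxel_table[["x", "y", "z"]].to_numpy(int)
    dims = coords.max(axis=0) + 1
    if len(voxel_table) != int(np.prod(dims)):
        raise ValueError("voxels do not fully tile the bounding grid")
    vol = np.zeros(dims, dtype=float)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = np.asarray(bsr_column, float)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
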