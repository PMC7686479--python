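"""Genotype containers, I/O, QC, allele harmonization, relatedness and ancestry MDS.

Dosage data are held as a subjects x variants matrix of alternate-allele
dosages in [0, 2] (NaN = missing) together with per-variant metadata
(chromosome, position, ref/alt alleles, MAF, imputation INFO, missing rate).
Quality control follows the usual GWAS conventions: variants are retained
only when MAF and INFO strictly exceed their thresholds, strand-ambiguous
(A/T, C/G) variants and positional duplicates are dropped.

Relatedness is estimated as PIHAT (the expected proportion of the genome
shared identical by descent) via the method-of-moments IBD estimator from
identity-by-state counts given sample allele frequencies; population
structure is summarized by classical (Torgerson) multidimensional scaling of
the 1 - IBS-proportion distance matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import mean_impute

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "info", "missing_rate"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with variant metadata.

    dosages: float array (n_subjects, n_variants), alt-allele dosage in
        [0, 2], NaN marks missing.
    subject_ids: list of unique subject identifiers.
    variants: DataFrame with columns ``id, chrom, pos, ref, alt, maf,
        info, missing_rate`` (one row per dosage column, same order).
    """

    dosages: np.ndarray
    subject_ids: list
    variants: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D subjects x variants array")
        n_subj, n_var = self.dosages.shape
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length does not match dosage rows")
        if len(self.variants) != n_var:
            raise ValueError("variants table length does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table missing columns: {missing}")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        if (self.variants["pos"] < 0).any():
            raise ValueError("variant positions must be non-negative")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.nansum(bad) > 0:
            raise ValueError("non-missing dosages must lie within [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing values mean-imputed per variant."""
        return mean_impute(self.dosages)

    def subject_missing_rate(self) -> pd.Series:
        return pd.Series(
            np.isnan(self.dosages).mean(axis=1), index=list(self.subject_ids)
        )

    def take_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.subject_ids),
            self.variants.iloc[idx].reset_index(drop=True),
        )

    def take_subjects(self, keep_ids) -> "GenotypeMatrix":
        keep = [i for i, s in enumerate(self.subject_ids) if s in set(keep_ids)]
        return GenotypeMatrix(
            self.dosages[keep, :],
            [self.subject_ids[i] for i in keep],
            self.variants.copy(),
        )

    def empirical_maf(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_info: int
    n_removed_ambiguous: int
    n_removed_duplicate: int
    n_retained: int
    removed_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        total = (
            self.n_retained
            + self.n_removed_maf
            + self.n_removed_info
            + self.n_removed_ambiguous
            + self.n_removed_duplicate
        )
        if total != self.n_input:
            raise ValueError("QC accounting error: removals + retained != input")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for reason, ids in self.removed_ids.items():
            rows.extend({"variant_id": v, "reason": reason} for v in ids)
        return pd.DataFrame(rows, columns=["variant_id", "reason"])


@dataclass
class RelatednessResult:
    pihat: pd.DataFrame
    excluded_subjects: list  # list of (subject_id, reason)

    @property
    def excluded_ids(self) -> list:
        return [s for s, _ in self.excluded_subjects]


@dataclass
class AncestryComponents:
    components: pd.DataFrame  # subjects x k, columns C1..Ck
    variance_explained: np.ndarray


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, dosage_path, variant_path) -> None:
    """Write subjects x variants dosage TSV plus the variant-metadata sidecar."""
    df = pd.DataFrame(
        g.dosages, index=pd.Index(g.subject_ids, name="subject_id"),
        columns=g.variants["id"].tolist(),
    )
    df.to_csv(dosage_path, sep="\t", na_rep="NA")
    g.variants.to_csv(variant_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variant_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"])
    variants = pd.read_csv(variant_path, sep="\t")
    if list(df.columns) != variants["id"].astype(str).tolist():
        raise ValueError("dosage columns do not match variant metadata ids")
    return GenotypeMatrix(df.to_numpy(float), list(df.index), variants)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with a DS (dosage) FORMAT field.

    Hard genotypes are emitted alongside DS by rounding the dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO">\n')
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.subject_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in g.variants.iterrows():
            cells = []
            for d in g.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(round(d))]}:{d:.4g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\tINFO={row['info']:.4g}\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    dosages, meta = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(
                f"record {i + 1} ({var.CHROM}:{var.POS}): multiallelic records "
                "are not supported"
            )
        ds = None
        try:
            ds_arr = var.format("DS")
        except KeyError:
            ds_arr = None
        if ds_arr is not None:
            ds = np.asarray(ds_arr, dtype=float).reshape(-1)
        else:
            # fall back to hard alt-allele counts from GT
            gts = np.asarray(var.genotype.array())
            ploidy = gts.shape[1] - 1
            if ploidy != 2:
                raise ValueError(
                    f"record {i + 1} ({var.CHROM}:{var.POS}): mixed or "
                    f"non-diploid ploidy {ploidy}"
                )
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            ds = alleles.sum(axis=1)
        info_val = var.INFO.get("INFO")
        dosages.append(ds)
        meta.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "maf": np.nan,
                "info": np.nan if info_val is None else float(info_val),
                "missing_rate": float(np.isnan(ds).mean()),
            }
        )
    d = np.column_stack(dosages) if dosages else np.empty((len(subjects), 0))
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    g = GenotypeMatrix(d, subjects, variants)
    g.variants["maf"] = g.empirical_maf()
    return g


def read_genotypes(path, fmt: str = "vcf", variant_path=None) -> GenotypeMatrix:
    """Read genotypes from VCF (DS field preferred, else GT counts) or dosage TSV."""
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage_tsv":
        if variant_path is None:
            raise ValueError("dosage_tsv format requires variant_path")
        return read_dosage_tsv(path, variant_path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def is_strand_ambiguous(ref, alt) -> np.ndarray:
    ref = np.asarray(ref, dtype=str)
    alt = np.asarray(alt, dtype=str)
    comp = np.vectorize(lambda a: _COMPLEMENT.get(a, "N"))(ref)
    return comp == alt


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    info_min: float = 0.80,
    drop_ambiguous: bool = True,
    drop_duplicates: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Variant QC: keep maf > maf_min AND info > info_min (strict), drop
    strand-ambiguous (A/T, C/G) variants and later positional duplicates.

    A variant failing several rules is counted once, in the order
    MAF -> INFO -> ambiguous -> duplicate.
    """
    v = g.variants
    fail_maf = ~(v["maf"].to_numpy(float) > maf_min)
    fail_info = ~(v["info"].to_numpy(float) > info_min)
    ambiguous = (
        is_strand_ambiguous(v["ref"], v["alt"])
        if drop_ambiguous
        else np.zeros(len(v), bool)
    )
    if drop_duplicates:
        key = [
            (c, p, frozenset((r, a)))
            for c, p, r, a in zip(v["chrom"], v["pos"], v["ref"], v["alt"])
        ]
        duplicate = pd.Series(key).duplicated(keep="first").to_numpy()
    else:
        duplicate = np.zeros(len(v), bool)

    reason = np.full(len(v), "", dtype=object)
    for name, mask in [
        ("maf", fail_maf),
        ("info", fail_info),
        ("ambiguous", ambiguous),
        ("duplicate", duplicate),
    ]:
        reason[(reason == "") & mask] = name
    keep = reason == ""
    removed_ids = {
        name: v.loc[reason == name, "id"].tolist()
        for name in ("maf", "info", "ambiguous", "duplicate")
    }
    report = QCReport(
        n_input=len(v),
        n_removed_maf=len(removed_ids["maf"]),
        n_removed_info=len(removed_ids["info"]),
        n_removed_ambiguous=len(removed_ids["ambiguous"]),
        n_removed_duplicate=len(removed_ids["duplicate"]),
        n_retained=int(keep.sum()),
        removed_ids=removed_ids,
    )
    if report.n_retained == 0:
        logger.warning("QC removed every variant")
    return g.take_variants(keep), report


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize(g: GenotypeMatrix, table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align a weight/summary-statistics table to the genotype alt allele.

    The table needs columns ``variant_id`` (or ``id``), ``effect_allele``,
    ``other_allele`` and one effect column (``weight`` or ``beta``). When the
    effect allele equals the genotype ref allele the effect is negated and
    the alleles swapped; variants whose allele set does not match, or that
    are absent from the genotypes, are dropped and reported.
    """
    t = table.copy()
    id_col = "variant_id" if "variant_id" in t.columns else "id"
    effect_col = "weight" if "weight" in t.columns else "beta"
    vmeta = g.variants.set_index("id")
    report = {"n_input": len(t), "flipped": [], "dropped": []}
    keep_rows, flipped = [], []
    for idx, row in t.iterrows():
        vid = row[id_col]
        if vid not in vmeta.index:
            report["dropped"].append(vid)
            continue
        ref, alt = vmeta.at[vid, "ref"], vmeta.at[vid, "alt"]
        ea, oa = row["effect_allele"], row["other_allele"]
        if ea == alt and oa == ref:
            keep_rows.append(idx)
            flipped.append(False)
        elif ea == ref and oa == alt:
            keep_rows.append(idx)
            flipped.append(True)
            report["flipped"].append(vid)
        else:
            report["dropped"].append(vid)
    out = t.loc[keep_rows].copy()
    flipped = np.asarray(flipped, bool)
    if len(out):
        out.loc[flipped, effect_col] = -out.loc[flipped, effect_col].astype(float)
        ea = out["effect_allele"].copy()
        out.loc[flipped, "effect_allele"] = out.loc[flipped, "other_allele"]
        out.loc[flipped, "other_allele"] = ea[flipped]
    report["n_retained"] = len(out)
    if report["dropped"]:
        logger.info("harmonize dropped %d variants", len(report["dropped"]))
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Relatedness (PIHAT)
# ---------------------------------------------------------------------------

def _hard_calls(g: GenotypeMatrix) -> np.ndarray:
    return np.clip(np.round(g.imputed()), 0, 2).astype(np.int8)


def pihat_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments PIHAT = P(IBD=1)/2 + P(IBD=2) from IBS counts.

    Uses sample alt-allele frequencies; estimates are clamped to [0, 1]
    (no small-sample frequency corrections).
    """
    calls = _hard_calls(g)
    n, m = calls.shape
    p = calls.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants are monomorphic; PIHAT is undefined")
    calls = calls[:, poly]
    p = p[poly]
    q = 1.0 - p

    a0 = (calls == 0).astype(float)
    a1 = (calls == 1).astype(float)
    a2 = (calls == 2).astype(float)
    # pairwise IBS-state counts via indicator cross-products
    n_ibs0 = a0 @ a2.T + a2 @ a0.T
    n_ibs1 = a1 @ (a0 + a2).T + (a0 + a2) @ a1.T
    n_ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T

    # expected per-variant IBS-state probabilities given IBD state Z
    e0_z0 = np.sum(2 * p**2 * q**2)
    e1_z0 = np.sum(4 * p**3 * q + 4 * p * q**3)
    e2_z0 = np.sum(p**4 + q**4 + 4 * p**2 * q**2)
    e1_z1 = np.sum(2 * p**2 * q + 2 * p * q**2)
    e2_z1 = np.sum(p**3 + q**3 + p**2 * q + p * q**2)
    m_used = calls.shape[1]

    z0 = n_ibs0 / e0_z0
    z1 = (n_ibs1 - z0 * e1_z0) / e1_z1
    z2 = (n_ibs2 - z0 * e2_z0 - z1 * e2_z1) / m_used
    pihat = z1 / 2.0 + z2
    n_clamped = int(np.sum((pihat < 0) | (pihat > 1)) - n)  # diagonal excluded
    if n_clamped > 0:
        logger.info("clamped %d off-diagonal PIHAT estimates into [0, 1]", n_clamped)
    pihat = np.clip(pihat, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    return (pihat + pihat.T) / 2.0


def exclude_related(
    pihat: pd.DataFrame, missing_rate: pd.Series, pihat_max: float = 0.2
) -> list:
    """For each pair with PIHAT strictly above pihat_max, drop the member with
    the higher genotype missing rate (tie: lexicographically later id)."""
    ids = list(pihat.index)
    excluded: list = []
    mat = pihat.to_numpy(float)
    order = [
        (i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))
        if mat[i, j] > pihat_max
    ]
    out = set()
    for i, j in sorted(order, key=lambda ij: -mat[ij[0], ij[1]]):
        a, b = ids[i], ids[j]
        if a in out or b in out:
            continue
        ma, mb = missing_rate.get(a, 0.0), missing_rate.get(b, 0.0)
        if ma > mb:
            drop = a
        elif mb > ma:
            drop = b
        else:
            drop = max(a, b)
        out.add(drop)
        excluded.append((drop, f"PIHAT {mat[i, j]:.3f} with {(b if drop == a else a)}"))
    return excluded


def estimate_relatedness(g: GenotypeMatrix, pihat_max: float = 0.2) -> RelatednessResult:
    if g.n_subjects < 2:
        raise ValueError("relatedness needs at least 2 subjects")
    mat = pihat_matrix(g)
    pihat = pd.DataFrame(mat, index=list(g.subject_ids), columns=list(g.subject_ids))
    excluded = exclude_related(pihat, g.subject_missing_rate(), pihat_max)
    return RelatednessResult(pihat=pihat, excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# Ancestry MDS
# ---------------------------------------------------------------------------

def ibs_distance(g: GenotypeMatrix) -> np.ndarray:
    """d = 1 - (mean pairwise IBS)/2 on hard calls."""
    calls = _hard_calls(g).astype(float)
    n, m = calls.shape
    diff = np.abs(calls[:, None, :] - calls[None, :, :]) if n * n * m < 5e7 else None
    if diff is not None:
        ibs = 2.0 - diff.mean(axis=2)
    else:  # blocked computation for large panels
        ibs = np.zeros((n, n))
        for start in range(0, m, 1000):
            block = calls[:, start : start + 1000]
            ibs += (2.0 - np.abs(block[:, None, :] - block[None, :, :])).sum(axis=2)
        ibs /= m
    return 1.0 - ibs / 2.0


class IBSMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling of genotype IBS distances.

    Mirrors the PLINK ``--mds-plot`` convention: distance = 1 - IBS
    proportion, double-centered squared distances, eigendecomposition,
    components scaled by sqrt(eigenvalue) and ordered by eigenvalue.

    Attributes (after fit): ``embedding_`` (n_subjects, k),
    ``variance_explained_`` (k,), ``eigenvalues_``.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, g: GenotypeMatrix, y=None):
        k = self.n_components
        if k >= g.n_subjects:
            raise ValueError(
                f"n_components={k} must be < n_subjects={g.n_subjects}"
            )
        D = ibs_distance(g)
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos_sum = evals[evals > 0].sum()
        lam = np.clip(evals[:k], 0.0, None)
        comps = evecs[:, :k] * np.sqrt(lam)
        self.eigenvalues_ = evals
        self.embedding_ = comps
        self.variance_explained_ = (
            lam / pos_sum if pos_sum > 0 else np.zeros(k)
        )
        self.subject_ids_ = list(g.subject_ids)
        return self

    def fit_transform(self, g: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(g).embedding_


def mds_components(g: GenotypeMatrix, k: int = 10) -> AncestryComponents:
    """Top-k ancestry components (C1..Ck) from classical MDS of IBS distances."""
    est = IBSMDS(n_components=k).fit(g)
    comps = pd.DataFrame(
        est.embedding_,
        index=list(g.subject_ids),
        columns=[f"C{i + 1}" for i in range(k)],
    )
    return AncestryComponents(components=comps, variance_explained=est.variance_explained_)


def assign_reference_clusters(
    components: np.ndarray,
    ref_components: np.ndarray,
    ref_labels,
    target_label,
    distance_quantile: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid population assignment in MDS space.

    Each study subject is assigned to the closest reference-population
    centroid; subjects whose distance to the ``target_label`` centroid
    exceeds that population's ``distance_quantile`` of reference distances
    are flagged for exclusion. Returns (assigned_labels, keep_mask).
    """
    ref_labels = np.asarray(ref_labels)
    cents = {
        lab: ref_components[ref_labels == lab].mean(axis=0)
        for lab in np.unique(ref_labels)
    }
    labs = np.array(list(cents))
    cmat = np.stack([cents[lab] for lab in labs])
    d = np.linalg.norm(components[:, None, :] - cmat[None, :, :], axis=2)
    assigned = labs[np.argmin(d, axis=1)]
    ref_d = np.linalg.norm(
        ref_components[ref_labels == target_label] - cents[target_label], axis=1
    )
    cutoff = np.quantile(ref_d, distance_quantile)
    d_target = np.linalg.norm(components - cents[target_label], axis=1)
    keep = (assigned == target_label) & (d_target <= cutoff)
    return assigned, keep
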