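"""Synthetic study generator.

Emulates the design of a genotype -> imputed-expression -> brain -> symptom
study: LD-blocked biallelic dosages, sparse cis-eQTL weight tables, GWAS
summary statistics, three task conditions (emotional faces, neutral faces,
shapes) acquired in two sex groups with a planted score-correlated latent
variable in voxel space, and symptom scales carrying a planted indirect
(mediation) path from the polygenic score through the brain pattern to
anhedonia.

Genotypes use a blockwise Gaussian copula: two latent haplotype draws share
a per-block factor with loading sqrt(r), are thresholded at the normal
quantile of each variant's minor-allele frequency, and summed to a dosage
in {0, 1, 2}. This gives tunable within-block LD and exact binomial
marginals without attempting coalescent realism.

The planted brain signal is rank-1: signal voxels form one contiguous block
on the 3-D grid with a common unit-norm salience, and each (group,
condition) cell contributes ``amplitude x standardized score x salience``
plus white noise. ``planted_effects`` entries are target per-voxel
score-activation correlations; they are converted to cell amplitudes
internally. ``mediation_a`` instead fixes the raw regression slope of the
true brainscore on the standardized score for the designated mediation cell,
so the planted indirect effect a*b is a raw-scale quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import rng_for
from .genotypes import VARIANT_COLUMNS, GenotypeMatrix

DEFAULT_CONDITIONS = ("emotional_faces", "neutral_faces", "shapes")
DEFAULT_GROUPS = ("female", "male")

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# stream ids for deriving independent RNG streams from one seed
_S_GENO, _S_WEIGHTS, _S_GWAS, _S_BRAIN, _S_SYMPTOM, _S_GROUPS = range(6)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (478 subjects split into female/male groups, three face-task conditions,
    76 scored genes)."""

    n_subjects: int = 478
    n_variants: int = 3000
    ld_block_size: int = 10
    within_block_r: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 76
    snps_per_gene: int = 3
    n_voxels: int = 300
    grid_dims: tuple = (5, 6, 10)
    conditions: tuple = DEFAULT_CONDITIONS
    groups: tuple = DEFAULT_GROUPS
    planted_effects: dict = field(
        default_factory=lambda: {
            ("female", "neutral_faces"): -0.3,
            ("male", "emotional_faces"): 0.15,
            ("male", "shapes"): 0.15,
        }
    )
    signal_fraction: float = 0.1
    noise_sd: float = 1.0
    mediation_a: float = 0.0
    mediation_b: float = 0.1
    mediation_cell: tuple | None = None
    symptom_cross_corr: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_subjects", "n_variants", "ld_block_size", "n_genes",
            "snps_per_gene", "n_voxels",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError(f"within_block_r must lie in [0, 1), got {self.within_block_r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if len(self.grid_dims) != 3 or any(int(d) <= 0 for d in self.grid_dims):
            raise ValueError(f"grid_dims must be 3 positive integers, got {self.grid_dims}")
        if int(np.prod(self.grid_dims)) < self.n_voxels:
            raise ValueError("grid_dims product must be >= n_voxels")
        if not (0.0 < self.signal_fraction <= 1.0):
            raise ValueError(f"signal_fraction must lie in (0, 1], got {self.signal_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        for cell, r in self.planted_effects.items():
            g, c = cell
            if g not in self.groups:
                raise ValueError(f"planted_effects group {g!r} not in groups")
            if c not in self.conditions:
                raise ValueError(f"planted_effects condition {c!r} not in conditions")
            if not (-1.0 < r < 1.0):
                raise ValueError(f"planted_effects[{cell}] must lie in (-1, 1), got {r}")
        if self.snps_per_gene > self.n_variants:
            raise ValueError("snps_per_gene cannot exceed n_variants")

    @property
    def mediation_cell_resolved(self) -> tuple:
        if self.mediation_cell is not None:
            return tuple(self.mediation_cell)
        cond = self.conditions[1] if len(self.conditions) > 1 else self.conditions[0]
        return (self.groups[0], cond)


@dataclass
class GroundTruth:
    """Planted quantities, recorded for parameter-recovery tests."""

    true_expression: pd.DataFrame | None = None
    true_voxel_salience: np.ndarray | None = None
    true_behavior_salience: dict | None = None
    causal_variants: set | None = None
    mediation_paths: tuple | None = None
    signal_voxels: np.ndarray | None = None
    true_brainscore: pd.Series | None = None

    def __post_init__(self):
        if self.true_voxel_salience is not None:
            nrm = np.linalg.norm(self.true_voxel_salience)
            if abs(nrm - 1.0) > 1e-8:
                raise ValueError("true_voxel_salience must have unit norm")
        if self.mediation_paths is not None:
            a, b, ab = self.mediation_paths
            if abs(ab - a * b) > 1e-12:
                raise ValueError("recorded a*b must equal a times b")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, seed=None) -> GenotypeMatrix:
    """LD-blocked biallelic dosages via a blockwise Gaussian copula."""
    config.validate()
    rng = rng_for(config.seed if seed is None else seed, _S_GENO)
    n, m = config.n_subjects, config.n_variants
    bs = config.ld_block_size
    r = config.within_block_r

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    n_blocks = int(np.ceil(m / bs))
    block_of = np.repeat(np.arange(n_blocks), bs)[:m]

    thresh = norm.ppf(mafs)
    dose = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        factor = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, m))
        z = np.sqrt(r) * factor[:, block_of] + np.sqrt(1.0 - r) * eps
        dose += (z < thresh[None, :]).astype(float)

    # positions: blocks tile chromosomes; 5 kb spacing inside a block,
    # 1 Mb gaps between blocks, <=30 blocks per chromosome
    blocks_per_chrom = 30
    chroms = (block_of // blocks_per_chrom + 1).astype(int)
    within = np.arange(m) % bs
    block_in_chrom = block_of % blocks_per_chrom
    pos = 1 + block_in_chrom * 1_000_000 + within * 5_000

    ref = _BASES[rng.integers(0, 4, size=m)]
    alt = np.empty(m, dtype=object)
    amb = rng.random(m) < 0.05
    for j in range(m):
        if amb[j]:
            alt[j] = _COMPLEMENT[ref[j]]
        else:
            choices = [b for b in "ACGT" if b != ref[j] and b != _COMPLEMENT[ref[j]]]
            alt[j] = choices[rng.integers(0, len(choices))]

    info = rng.uniform(0.5, 1.0, size=m)
    p_hat = dose.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": np.minimum(p_hat, 1 - p_hat),
            "info": info,
            "missing_rate": 0.0,
        },
        columns=VARIANT_COLUMNS,
    )
    return GenotypeMatrix(
        dose, [f"S{i + 1:04d}" for i in range(n)], variants
    )


# ---------------------------------------------------------------------------
# eQTL weights + DE-gene table
# ---------------------------------------------------------------------------

def simulate_eqtl_weights(
    genotypes: GenotypeMatrix, config: SimulationConfig, seed=None,
    flip_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sparse per-gene eQTL weight table and the implied true expression.

    Each gene gets ``snps_per_gene`` distinct variants with nonzero normal
    weights; ``flip_fraction`` of the rows report the ref allele as effect
    allele (weight sign adjusted) to exercise harmonization. The true
    expression is the harmonized dosage-by-weight linear combination.
    """
    config.validate()
    if config.snps_per_gene > genotypes.n_variants:
        raise ValueError("snps_per_gene cannot exceed the number of variants")
    rng = rng_for(config.seed if seed is None else seed, _S_WEIGHTS)
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    v = genotypes.variants
    rows = []
    expr = np.zeros((genotypes.n_subjects, config.n_genes))
    dose = genotypes.imputed()
    for gi, gene in enumerate(genes):
        idx = rng.choice(genotypes.n_variants, size=config.snps_per_gene, replace=False)
        w = rng.normal(0.0, 0.3, size=config.snps_per_gene)
        w[w == 0] = 0.1
        expr[:, gi] = dose[:, idx] @ w
        for j, wj in zip(idx, w):
            flip = rng.random() < flip_fraction
            ref, alt = v.at[j, "ref"], v.at[j, "alt"]
            rows.append(
                {
                    "gene_id": gene,
                    "variant_id": v.at[j, "id"],
                    "effect_allele": ref if flip else alt,
                    "other_allele": alt if flip else ref,
                    # weight is stated per effect allele; flipping the
                    # reported allele negates the stored weight so the
                    # harmonized model is unchanged
                    "weight": -wj if flip else wj,
                }
            )
    weights = pd.DataFrame(rows)
    true_expression = pd.DataFrame(
        expr, index=list(genotypes.subject_ids), columns=genes
    )
    return weights, true_expression


def simulate_de_table(gene_ids, seed=None) -> pd.DataFrame:
    """Differential-expression direction table (+1 up in cases, -1 down)."""
    rng = rng_for(seed, 17)
    direction = rng.choice([-1, 1], size=len(gene_ids))
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "direction": direction, "effect_weight": 1.0}
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_sumstats(
    genotypes: GenotypeMatrix, n_causal: int, seed=None, flip_fraction: float = 0.2,
) -> tuple[pd.DataFrame, set]:
    """Summary statistics with ``n_causal`` planted signals.

    Null variants get beta ~ N(0, 0.02) and p ~ U(0, 1]; causal variants get
    |beta| >= 0.1 and p = 10**-U(8, 15). Returns (sumstats, causal_id_set).
    """
    if n_causal > genotypes.n_variants:
        raise ValueError("n_causal cannot exceed the number of variants")
    rng = rng_for(seed, _S_GWAS)
    v = genotypes.variants
    m = genotypes.n_variants
    beta = rng.normal(0.0, 0.02, size=m)
    p = 1.0 - rng.random(m)  # uniform on (0, 1]
    causal_idx = rng.choice(m, size=n_causal, replace=False) if n_causal else np.array([], int)
    if n_causal:
        b = rng.normal(0.0, 0.3, size=n_causal)
        b = np.where(np.abs(b) < 0.1, np.sign(b) * 0.1 + np.where(b == 0, 0.1, 0), b)
        beta[causal_idx] = b
        p[causal_idx] = 10.0 ** (-rng.uniform(8, 15, size=n_causal))
    flip = rng.random(m) < flip_fraction
    ea = np.where(flip, v["ref"], v["alt"])
    oa = np.where(flip, v["alt"], v["ref"])
    beta = np.where(flip, -beta, beta)
    ss = pd.DataFrame(
        {
            "id": v["id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "p": p,
            "maf": v["maf"],
            "info": v["info"],
        }
    )
    causal = set(v.loc[causal_idx, "id"])
    return ss, causal


# ---------------------------------------------------------------------------
# brain activation data
# ---------------------------------------------------------------------------

@dataclass
class ActivationData:
    """Per-condition subjects x voxels activation with grid coordinates."""

    matrices: dict  # condition label -> (n_subjects, n_voxels) array
    subject_ids: list
    voxel_table: pd.DataFrame  # voxel_id, x, y, z
    group: pd.Series  # subject id -> group label

    def __post_init__(self):
        shapes = {c: m.shape for c, m in self.matrices.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"condition matrices disagree in shape: {shapes}")
        n_subj, n_vox = next(iter(shapes.values()))
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length does not match activation rows")
        if len(self.voxel_table) != n_vox:
            raise ValueError("voxel_table length does not match activation columns")
        coords = list(zip(self.voxel_table["x"], self.voxel_table["y"], self.voxel_table["z"]))
        if len(set(coords)) != len(coords):
            raise ValueError("voxel coordinates must be unique")
        self.group = pd.Series(self.group)
        self.group.index = list(self.subject_ids)

    @property
    def conditions(self) -> list:
        return list(self.matrices)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_table)

    def take_subjects(self, ids) -> "ActivationData":
        ids = [s for s in self.subject_ids if s in set(ids)]
        rows = [self.subject_ids.index(s) for s in ids]
        return ActivationData(
            matrices={c: m[rows] for c, m in self.matrices.items()},
            subject_ids=ids,
            voxel_table=self.voxel_table,
            group=self.group.loc[ids],
        )


def _voxel_grid(config: SimulationConfig) -> pd.DataFrame:
    dims = tuple(int(d) for d in config.grid_dims)
    xs, ys, zs = np.unravel_index(np.arange(config.n_voxels), dims)
    return pd.DataFrame(
        {
            "voxel_id": [f"V{i + 1:05d}" for i in range(config.n_voxels)],
            "x": xs, "y": ys, "z": zs,
        }
    )


def _cell_amplitude(r: float, noise_sd: float, m_signal: int) -> float:
    """Amplitude c giving per-voxel correlation r under uniform salience.

    With salience 1/sqrt(m) and white noise sd s, corr = c/sqrt(m) /
    sqrt(c^2/m + s^2) = r  =>  c = s * r * sqrt(m) / sqrt(1 - r^2).
    In the noiseless limit the correlation is sign(r) for any amplitude.
    """
    if noise_sd == 0:
        return float(np.sign(r)) * np.sqrt(m_signal)
    return noise_sd * r * np.sqrt(m_signal) / np.sqrt(1.0 - r**2)


def simulate_brain_data(
    score, groups, config: SimulationConfig, seed=None
) -> tuple[ActivationData, GroundTruth]:
    """Plant a rank-1 score-correlated pattern into voxel activations.

    ``score`` is a per-subject array or Series (standardized internally);
    ``groups`` is a per-subject label sequence drawn from config.groups.
    """
    config.validate()
    score = pd.Series(score)
    groups = pd.Series(list(groups), index=score.index)
    unknown = set(groups) - set(config.groups)
    if unknown:
        raise ValueError(f"group labels not in config.groups: {sorted(unknown)}")
    if score.isna().any():
        raise ValueError("score must be defined for every subject")
    rng = rng_for(config.seed if seed is None else seed, _S_BRAIN)
    n = len(score)
    z = (score - score.mean()) / score.std(ddof=0)
    z = z.to_numpy()

    m_signal = max(int(round(config.signal_fraction * config.n_voxels)), 1)
    signal_idx = np.arange(m_signal)  # raster-order prefix: one connected block
    salience = np.zeros(config.n_voxels)
    salience[signal_idx] = 1.0 / np.sqrt(m_signal)

    amplitudes = {
        cell: _cell_amplitude(r, config.noise_sd, m_signal)
        for cell, r in config.planted_effects.items()
    }
    if config.mediation_a != 0.0:
        # brainscore = activation @ salience = amplitude * z + N(0, noise_sd),
        # so the cell amplitude IS the raw score -> brainscore path a
        amplitudes[config.mediation_cell_resolved] = config.mediation_a

    matrices = {}
    for cond in config.conditions:
        act = rng.normal(0.0, config.noise_sd, size=(n, config.n_voxels))
        for grp in config.groups:
            amp = amplitudes.get((grp, cond), 0.0)
            if amp == 0.0:
                continue
            rows = (groups == grp).to_numpy()
            act[np.ix_(rows, signal_idx)] += (
                amp * z[rows, None] * salience[signal_idx][None, :]
            )
        matrices[cond] = act

    behavior = {
        cell: amplitudes.get(cell, 0.0) / np.sqrt(m_signal)
        for cell in ((g, c) for g in config.groups for c in config.conditions)
    }
    med_cell = config.mediation_cell_resolved
    true_brainscore = pd.Series(
        matrices[med_cell[1]] @ salience if med_cell[1] in matrices else np.zeros(n),
        index=list(score.index),
    )
    act_data = ActivationData(
        matrices=matrices,
        subject_ids=list(score.index),
        voxel_table=_voxel_grid(config),
        group=groups,
    )
    truth = GroundTruth(
        true_voxel_salience=salience,
        true_behavior_salience=behavior,
        signal_voxels=signal_idx,
        mediation_paths=(
            config.mediation_a, config.mediation_b,
            config.mediation_a * config.mediation_b,
        ),
        true_brainscore=true_brainscore,
    )
    return act_data, truth


# ---------------------------------------------------------------------------
# symptoms
# ---------------------------------------------------------------------------

SYMPTOM_COLUMNS = [
    "anhedonia", "anxious_arousal", "general_distress_depression",
    "general_distress_anxiety", "ctq_total", "life_events_total", "sex", "age",
]


def simulate_symptoms(
    brainscore, config: SimulationConfig, groups=None, seed=None
) -> pd.DataFrame:
    """Symptom table with anhedonia = b * brainscore + noise.

    The other MASQ subscales and the stress scales share a configurable
    correlation (``symptom_cross_corr``) with anhedonia but carry no extra
    planted brain path; scales stay continuous.
    """
    rng = rng_for(config.seed if seed is None else seed, _S_SYMPTOM)
    bs = pd.Series(brainscore)
    if bs.isna().any():
        raise ValueError("brainscore must be defined for every subject")
    n = len(bs)
    anhedonia = config.mediation_b * bs.to_numpy() + rng.normal(0, config.noise_sd, n)
    sd = anhedonia.std()
    z_anh = (anhedonia - anhedonia.mean()) / (sd if sd > 0 else 1.0)
    rho = config.symptom_cross_corr

    def correlated(rho):
        return rho * z_anh + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(n)

    if groups is None:
        groups = pd.Series(
            np.array(config.groups)[rng.integers(0, len(config.groups), n)],
            index=bs.index,
        )
    else:
        groups = pd.Series(list(groups), index=bs.index)
    out = pd.DataFrame(
        {
            "anhedonia": anhedonia,
            "anxious_arousal": correlated(rho),
            "general_distress_depression": correlated(rho),
            "general_distress_anxiety": correlated(rho),
            "ctq_total": correlated(rho * 0.67),
            "life_events_total": correlated(rho * 0.67),
            "sex": groups.to_numpy(),
            "age": rng.normal(19.79, 1.24, n),
        },
        index=list(bs.index),
    )
    out.index.name = "subject_id"
    return out


# ---------------------------------------------------------------------------
# whole-study convenience + writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    weights: pd.DataFrame
    de_table: pd.DataFrame
    sumstats: pd.DataFrame
    score: pd.Series
    activations: ActivationData
    symptoms: pd.DataFrame
    truth: GroundTruth


def simulate_study(config: SimulationConfig, n_causal: int = 20) -> SimulatedStudy:
    """Generate every pipeline input from one config + seed.

    The score planted into the brain data is the transcriptome-based risk
    score computed from the simulated genotypes and weights, so the chain
    genotype -> expression -> score -> brain -> symptom is closed.
    """
    from .scoring import compute_tprs, impute_expression
    from .genotypes import harmonize, qc_filter

    g = simulate_genotypes(config)
    weights, true_expr = simulate_eqtl_weights(g, config)
    de = simulate_de_table(true_expr.columns, seed=config.seed)
    ss, causal = simulate_gwas_sumstats(g, n_causal=n_causal, seed=config.seed)
    # the planted score mirrors the analysis order: variant QC first, then
    # imputation and scoring, so the analysis can recover the score exactly
    g_qc, _ = qc_filter(g)
    w_harm, _ = harmonize(g_qc, weights)
    expr = impute_expression(g_qc, w_harm)
    score = compute_tprs(expr, de).scores

    rng = rng_for(config.seed, _S_GROUPS)
    groups = pd.Series(
        np.array(config.groups)[
            rng.permutation(np.arange(len(score)) % len(config.groups))
        ],
        index=score.index,
    )
    act, truth = simulate_brain_data(score, groups, config)
    truth.true_expression = true_expr
    truth.causal_variants = causal
    symptoms = simulate_symptoms(truth.true_brainscore, config, groups=groups)
    return SimulatedStudy(
        config=config, genotypes=g, weights=weights, de_table=de, sumstats=ss,
        score=score, activations=act, symptoms=symptoms, truth=truth,
    )


def write_activations(act: ActivationData, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cond, mat in act.matrices.items():
        pd.DataFrame(
            mat, index=pd.Index(act.subject_ids, name="subject_id"),
            columns=act.voxel_table["voxel_id"].tolist(),
        ).to_csv(outdir / f"activation_{cond}.tsv", sep="\t")
    act.voxel_table.to_csv(outdir / "voxels.tsv", sep="\t", index=False)
    act.group.rename("group").to_frame().rename_axis("subject_id").to_csv(
        outdir / "groups.tsv", sep="\t"
    )


def read_activations(outdir) -> ActivationData:
    from pathlib import Path

    outdir = Path(outdir)
    voxels = pd.read_csv(outdir / "voxels.tsv", sep="\t")
    groups = pd.read_csv(outdir / "groups.tsv", sep="\t", index_col=0)["group"]
    matrices = {}
    subject_ids = None
    for f in sorted(outdir.glob("activation_*.tsv")):
        cond = f.stem.replace("activation_", "")
        df = pd.read_csv(f, sep="\t", index_col=0)
        matrices[cond] = df.to_numpy(float)
        subject_ids = list(df.index)
    return ActivationData(
        matrices=matrices, subject_ids=subject_ids, voxel_table=voxels,
        group=groups.loc[subject_ids],
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write every simulated input in the package's TSV layout."""
    from pathlib import Path

    from .genotypes import write_dosage_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dosage_tsv(study.genotypes, outdir / "dosages.tsv", outdir / "variants.tsv")
    study.weights.to_csv(outdir / "eqtl_weights.tsv", sep="\t", index=False)
    study.de_table.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
    ss = study.sumstats.rename(
        columns={
            "id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
            "other_allele": "A2", "beta": "BETA", "p": "P", "maf": "FRQ",
            "info": "INFO",
        }
    )
    ss.to_csv(outdir / "sumstats.tsv", sep="\t", index=False)
    study.score.rename("score").to_frame().rename_axis("subject_id").to_csv(
        outdir / "tprs.tsv", sep="\t"
    )
    write_activations(study.activations, outdir / "activations")
    study.symptoms.to_csv(outdir / "symptoms.tsv", sep="\t")
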