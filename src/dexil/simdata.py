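"""Synthetic paired-factorial RNA-seq generator with planted ground truth.

Emulates a 2x2 air-liquid-interface experiment: primary airway epithelial
cultures from several donors, each exposed to control, IL-17A, dexamethasone,
or the combination, with bulk RNA-seq counts plus a FITC-dextran-style
epithelial-permeability phenotype. Counts are negative binomial with donor
block effects; genes fall into classes that reproduce the qualitative
structure of the study: IL-17A-responsive genes that are mostly resistant to
dexamethasone, dexamethasone-responsive genes suppressed by IL-17A, and a
"cilia" gene set whose expression is coupled to the permeability phenotype.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

GENE_CLASSES = (
    "dex_only",
    "il17_down",
    "il17_up_resistant",
    "il17_up_sensitive",
    "interaction_only",
    "null",
)

#: Default gene-class mixture. The study found many IL-17A genes (mostly
#: dexamethasone-resistant), few dexamethasone genes, and very few pure
#: interaction genes; the fractions mirror that imbalance.
DEFAULT_CLASS_FRACTIONS = {
    "il17_up_resistant": 0.10,
    "il17_up_sensitive": 0.02,
    "il17_down": 0.05,
    "dex_only": 0.02,
    "interaction_only": 0.01,
    "null": 0.80,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Effects are in log2 units throughout.  ``dispersion_a0``/``a1`` define the
    mean-dispersion trend alpha(mu) = a0 + a1/mu.  Phenotype parameters follow
    P = base + gain * IL17 * (1 - rescue * DEX) + noise, on a normalized
    concentration scale in [0, 1].
    """

    n_genes: int = 2000
    n_donors: int = 4
    baseline_meanlog: float = 5.5
    baseline_sdlog: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    donor_sd: float = 0.25
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    pheno_base: float = 0.2
    pheno_il17_gain: float = 0.6
    pheno_dex_rescue: float = 0.8
    pheno_noise_sd: float = 0.05
    n_cilia_genes: int = 50
    cilia_coupling: float = 2.0
    libsize_sdlog: float = 0.0
    dex_suppression: bool = True
    seed: int = 0

    def validate(self) -> None:
        fracs = self.class_fractions
        unknown = set(fracs) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total!r}, expected 1")
        if any(v < 0 for v in fracs.values()):
            raise ValueError("class_fractions must be non-negative")
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.dispersion_a0 <= 0:
            raise ValueError("dispersion_a0 must be > 0")
        n_nonzero = sum(1 for v in fracs.values() if v > 0)
        if self.n_genes < n_nonzero:
            raise ValueError(
                f"n_genes={self.n_genes} below number of populated classes"
            )


@dataclass
class SimTruth:
    """Planted per-gene ground truth, row-aligned with the count matrix."""

    table: pd.DataFrame  # gene_id, class, beta_il17, beta_dex, beta_int, mu, alpha, cilia_member

    def genes_in_class(self, cls: str) -> pd.Index:
        return pd.Index(self.table.loc[self.table["class"] == cls, "gene_id"])


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus sample annotations.

    ``samples`` columns: sample_id, donor, il17, dex, permeability (NaN when
    no phenotype was simulated/measured).
    """

    counts: pd.DataFrame  # genes x samples, index gene_id
    samples: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        validate_count_matrix(self.counts, self.samples)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def validate_count_matrix(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    if not counts.columns.equals(samples.index):
        missing = counts.columns.difference(samples.index).tolist()
        extra = samples.index.difference(counts.columns).tolist()
        raise ValueError(
            f"sample mismatch between counts and annotations: "
            f"missing annotations for {missing}, unmatched annotations {extra}"
        )
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("counts must be integers")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    cells = samples.groupby(["donor", "il17", "dex"]).size()
    if (cells != 1).any():
        bad = cells[cells != 1].index.tolist()
        raise ValueError(f"design cells not observed exactly once per donor: {bad}")


def allocate_classes(fracs: dict, n_genes: int) -> dict:
    """Largest-remainder allocation of genes to classes.

    Ties in the fractional remainder are broken by class name order so the
    allocation is deterministic.
    """
    names = sorted(fracs)
    quotas = np.array([fracs[c] * n_genes for c in names])
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = n_genes - int(base.sum())
    # stable sort on (-remainder, name order)
    order = sorted(range(len(names)), key=lambda i: (-remainder[i], names[i]))
    for i in order[:short]:
        base[i] += 1
    return {c: int(b) for c, b in zip(names, base)}


def _plant_effects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    alloc = allocate_classes(cfg.class_fractions, n)
    classes = np.concatenate(
        [np.repeat(c, alloc.get(c, 0)) for c in GENE_CLASSES]
    )
    perm = rng.permutation(n)
    classes = classes[perm]

    mag = rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd, size=n)
    mag = np.maximum(np.abs(mag), 0.1)
    sign = rng.choice([-1.0, 1.0], size=n)

    b_il17 = np.zeros(n)
    b_dex = np.zeros(n)
    b_int = np.zeros(n)

    up_r = classes == "il17_up_resistant"
    up_s = classes == "il17_up_sensitive"
    down = classes == "il17_down"
    dexo = classes == "dex_only"
    inter = classes == "interaction_only"

    b_il17[up_r] = mag[up_r]
    b_il17[up_s] = mag[up_s]
    b_int[up_s] = -mag[up_s]  # combination effect cancels back to baseline
    b_il17[down] = -mag[down]
    b_dex[dexo] = mag[dexo] * sign[dexo]
    if cfg.dex_suppression:
        b_int[dexo] = -b_dex[dexo]  # IL-17A abolishes the dex response
    b_int[inter] = mag[inter] * sign[inter]
    return pd.DataFrame(
        {"class": classes, "beta_il17": b_il17, "beta_dex": b_dex, "beta_int": b_int}
    )


def _sample_annotations(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for d in range(cfg.n_donors):
        for il17 in (0, 1):
            for dex in (0, 1):
                cond = {(0, 0): "ctrl", (1, 0): "il17", (0, 1): "dex", (1, 1): "combo"}[
                    (il17, dex)
                ]
                rows.append(
                    {
                        "sample_id": f"D{d + 1}_{cond}",
                        "donor": f"D{d + 1}",
                        "il17": il17,
                        "dex": dex,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_phenotype(
    cfg: SimConfig, samples: pd.DataFrame, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate the permeability phenotype from the condition flags.

    P = base + gain * IL17 * (1 - rescue * DEX) + Normal(0, noise_sd):
    IL-17A raises permeability (barrier disruption) and dexamethasone rescues
    a ``rescue`` fraction of that rise, mirroring the barrier-function result.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    il17 = samples["il17"].to_numpy(float)
    dex = samples["dex"].to_numpy(float)
    p = cfg.pheno_base + cfg.pheno_il17_gain * il17 * (1.0 - cfg.pheno_dex_rescue * dex)
    if cfg.pheno_noise_sd > 0:
        p = p + rng.normal(0.0, cfg.pheno_noise_sd, size=len(p))
    return p


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2; Poisson limit for tiny alpha."""
    mean = np.asarray(mean, float)
    alpha = np.broadcast_to(np.asarray(alpha, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        size = 1.0 / alpha[~tiny]
        p = size / (size + mean[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def generate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Generate a seeded count matrix and its planted truth.

    Counts for gene g in sample j are NB with mean
    ``s_j * mu_g * 2**(b_il17*I + b_dex*D + b_int*I*D + donor_effect + cilia_tilt)``
    and dispersion ``alpha_g = a0 + a1/mu_g``.  The cilia tilt couples the
    flagged gene set against the permeability phenotype (leakier barrier,
    lower cilia-gene expression).  Identical config and seed reproduce the
    matrix bit-exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    effects = _plant_effects(cfg, rng)
    n = cfg.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    mu = np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n))
    alpha = cfg.dispersion_a0 + cfg.dispersion_a1 / mu

    samples = _sample_annotations(cfg)
    m = len(samples)
    il17 = samples["il17"].to_numpy(float)
    dex = samples["dex"].to_numpy(float)
    donor_codes = pd.Categorical(samples["donor"]).codes
    donor_eff = rng.normal(0.0, cfg.donor_sd, size=cfg.n_donors)

    # cilia members drawn from null-class genes so the phenotype coupling is
    # the only planted signal on them
    cilia = np.zeros(n, dtype=bool)
    null_idx = np.flatnonzero((effects["class"] == "null").to_numpy())
    n_cilia = min(cfg.n_cilia_genes, len(null_idx))
    if n_cilia > 0:
        cilia[rng.choice(null_idx, size=n_cilia, replace=False)] = True

    pheno = generate_phenotype(cfg, samples, rng)

    log2_shift = (
        np.outer(effects["beta_il17"], il17)
        + np.outer(effects["beta_dex"], dex)
        + np.outer(effects["beta_int"], il17 * dex)
        + donor_eff[donor_codes][None, :]
    )
    if n_cilia > 0 and cfg.cilia_coupling != 0.0:
        tilt = -cfg.cilia_coupling * (pheno - pheno.mean())
        log2_shift[cilia, :] += tilt[None, :]

    size_factors = np.ones(m)
    if cfg.libsize_sdlog > 0:
        size_factors = np.exp(rng.normal(0.0, cfg.libsize_sdlog, size=m))

    mean = size_factors[None, :] * mu[:, None] * np.exp(LN2 * log2_shift)
    counts = _nb_sample(rng, mean, alpha[:, None])

    samples = samples.copy()
    samples["permeability"] = pheno
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
    )
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class": effects["class"].to_numpy(),
                "beta_il17": effects["beta_il17"].to_numpy(),
                "beta_dex": effects["beta_dex"].to_numpy(),
                "beta_int": effects["beta_int"].to_numpy(),
                "mu": mu,
                "alpha": alpha,
                "cilia_member": cilia,
            }
        ).reset_index(drop=True)
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture round trip

COUNTS_FILE = "counts.tsv"
SAMPLES_FILE = "samples.tsv"
TRUTH_FILE = "truth.tsv"


def write_fixture(matrix: CountMatrix, truth: SimTruth | None, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    counts = matrix.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(os.path.join(directory, COUNTS_FILE), sep="\t")
    samples = matrix.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(os.path.join(directory, SAMPLES_FILE), sep="\t", na_rep="NA")
    if truth is not None:
        truth.table.to_csv(os.path.join(directory, TRUTH_FILE), sep="\t", index=False)


def read_fixture(directory: str) -> tuple[CountMatrix, SimTruth | None]:
    from . import io as _io  # local import to avoid cycle

    matrix = _io.read_count_matrix(
        os.path.join(directory, COUNTS_FILE), os.path.join(directory, SAMPLES_FILE)
    )
    truth = None
    truth_path = os.path.join(directory, TRUTH_FILE)
    if os.path.exists(truth_path):
        # keep_default_na so the gene class named "null" survives parsing
        tbl = pd.read_csv(truth_path, sep="\t", keep_default_na=False, na_values=[""])
        tbl["cilia_member"] = tbl["cilia_member"].astype(str) == "True"
        truth = SimTruth(table=tbl)
    return matrix, truth
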