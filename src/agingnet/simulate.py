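"""Synthetic aging time-course RNA-seq generator with planted ground truth.

The generator emulates the statistical structure of a multi-tissue bulk
RNA-seq aging study at desk scale: negative-binomial counts over a 3-27
month age grid (9 ages x 2 sexes x ``n_per_group`` replicates), with

* sample-specific library sizes (log-normal), including planted shallow
  samples whose expected depth falls below the 4M-read filter,
* planted outlier samples whose gene labels are permuted within the sample
  (library size preserved, correlation structure destroyed — exactly what
  the sample-network z.K statistic detects),
* "trendy" genes with piecewise-linear log-mean age trajectories (continuous
  hinge form) and known breakpoints,
* co-expression modules driven by latent eigengene trajectories correlated
  with age or with sex, with per-gene loadings that make the top loaders the
  planted hub genes,
* biotype labels, and a GMT gene-set collection with planted enriched terms
  built predominantly from hub genes.

Counts are drawn as ``NB(mu, alpha)`` with
``mu_gs = sf_s * exp(b_g + f_g(t_s) + gamma_g*sex_s + lambda_g*e_m(t_s) + eps)``
and dispersion ``alpha(mu) = a1/mu + a0``.  Fixing the seed fixes the output
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, SampleTable
from .enrich import GeneSetCollection, write_gmt

DEFAULT_AGES = tuple(range(3, 28, 3))


@dataclass
class TrendySpec:
    """Planted piecewise-linear trajectory class (log-mean scale)."""

    n_genes: int = 200
    k: int = 1
    # slope magnitude per month (natural-log scale); sign alternates at
    # breakpoints to give V/inverted-V shapes with a large slope change
    slope: float = 0.25


@dataclass
class ModuleSpec:
    """Planted co-expression module driven by a latent eigengene."""

    name: str
    size: int = 100
    trait: str = "age"  # 'age' or 'sex'
    direction: int = 1
    shift_time: float = 15.0  # hinge of the age trajectory (months)
    within_cor: float = 0.6  # target mean gene-gene correlation
    hub_fraction: float = 0.3  # top loaders flagged as planted hubs
    eigengene_noise_sd: float = 0.3


@dataclass
class GMTSpec:
    n_terms: int = 40
    size_range: tuple[int, int] = (10, 60)
    planted_hub_fraction: float = 0.6  # composition of planted terms


@dataclass
class SimulationConfig:
    seed: int = 0
    n_per_group: int = 2  # mice per age x sex cell
    ages: tuple[float, ...] = DEFAULT_AGES
    tissue: str = "simulated"
    n_background: int = 700
    trendy: TrendySpec = field(default_factory=TrendySpec)
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(name="age_up", trait="age", direction=1, shift_time=15.0),
        ModuleSpec(name="age_down", trait="age", direction=-1, shift_time=12.0),
        ModuleSpec(name="sex_m", trait="sex", direction=1),
    )
    dispersion: tuple[float, float] = (0.05, 2.0)  # (a0, a1)
    log_library_mean: float = np.log(8e6)
    log_library_sd: float = 0.25
    shallow_depth: float = 2e6
    n_shallow: int = 2
    n_outlier: int = 1
    noise_sd: float = 0.1  # gene-sample log-scale Gaussian noise
    sex_effect_sd: float = 0.05  # baseline additive sex effect for all genes
    gmt: GMTSpec = field(default_factory=GMTSpec)

    @property
    def n_genes(self) -> int:
        return self.n_background + self.trendy.n_genes + sum(m.size for m in self.modules)


@dataclass
class TruthTables:
    genes: pd.DataFrame  # class, true_k, breakpoints, direction, module, hub, sex_sign
    samples: pd.DataFrame  # shallow, outlier flags
    terms: pd.DataFrame  # planted-enriched flag


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    samples: SampleTable
    truth: TruthTables
    gene_sets: GeneSetCollection


# ---------------------------------------------------------------------------
# Trajectory helpers
# ---------------------------------------------------------------------------

def hinge_trajectory(
    t: np.ndarray, breakpoints: tuple[float, ...], slopes: tuple[float, ...]
) -> np.ndarray:
    """Continuous piecewise-linear trajectory, zero at the first age.

    ``slopes`` has one entry per segment; the function is the integral of
    the step-wise slope, anchored at f(min t) = 0.
    """
    t = np.asarray(t, dtype=float)
    t0 = t.min()
    f = slopes[0] * (t - t0)
    for j, b in enumerate(breakpoints):
        f = f + (slopes[j + 1] - slopes[j]) * np.maximum(t - b, 0.0)
    return f


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Negative-binomial draw with dispersion alpha(mu) = a1/mu + a0."""
    mu = np.maximum(mu, 1e-8)
    alpha = a1 / mu + a0
    size = 1.0 / alpha  # NB 'number of failures' parameter
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Draw a full synthetic dataset with ground-truth tables.

    ``seed`` overrides ``config.seed`` when given.  The same seed always
    produces identical output.
    """
    cfg = config or SimulationConfig()
    for m in cfg.modules:
        if not (0 < m.within_cor < 1):
            raise ValueError(f"module {m.name}: within_cor must be in (0, 1)")
        if m.shift_time <= min(cfg.ages) or m.shift_time >= max(cfg.ages):
            raise ValueError(f"module {m.name}: shift_time must be interior to the age grid")
    if cfg.n_background < 0 or cfg.trendy.n_genes < 0:
        raise ValueError("negative gene class size")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # ----- samples -------------------------------------------------------
    sample_rows = []
    for age in cfg.ages:
        for sex_code, sex in ((0, "F"), (1, "M")):
            for rep in range(cfg.n_per_group):
                sample_rows.append(
                    {
                        "sample_id": f"s{age:02.0f}{sex}{rep + 1}",
                        "tissue": cfg.tissue,
                        "age_months": int(age),
                        "sex": sex,
                    }
                )
    meta = pd.DataFrame(sample_rows)
    n_samples = len(meta)
    t = meta["age_months"].to_numpy(dtype=float)
    sex = meta["sex"].map({"F": 0, "M": 1}).to_numpy(dtype=float)

    # ----- gene classes --------------------------------------------------
    gene_ids, klass, true_k, true_bps, true_dir = [], [], [], [], []
    module_of, hub_flag, sex_sign = [], [], []

    def add_gene(gid, cls, k=0, bps=(), direction="flat", module="", hub=False, ssign=0):
        gene_ids.append(gid)
        klass.append(cls)
        true_k.append(k)
        true_bps.append(",".join(f"{b:g}" for b in bps))
        true_dir.append(direction)
        module_of.append(module)
        hub_flag.append(hub)
        sex_sign.append(ssign)

    log_mu = np.zeros((cfg.n_genes, n_samples))
    base = rng.normal(np.log(200.0), 1.0, size=cfg.n_genes)  # relative abundance
    gamma = rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_genes)

    g = 0
    for _ in range(cfg.n_background):
        add_gene(f"BG{g:05d}", "background")
        g += 1

    interior = np.array(cfg.ages[1:-1], dtype=float)
    for i in range(cfg.trendy.n_genes):
        k = cfg.trendy.k
        bps = tuple(sorted(rng.choice(interior, size=k, replace=False)))
        s0 = cfg.trendy.slope * (1 if rng.random() < 0.5 else -1)
        slopes = tuple(s0 * (-1) ** j for j in range(k + 1))
        log_mu[g] += hinge_trajectory(t, bps, slopes)
        add_gene(
            f"TR{i:05d}", "trendy", k=k, bps=bps,
            direction="up" if s0 > 0 else "down",
        )
        g += 1

    eigengenes: dict[str, np.ndarray] = {}
    for m in cfg.modules:
        if m.trait == "age":
            core = _zscore(np.minimum(t, m.shift_time) * 0.3 + np.maximum(t - m.shift_time, 0.0))
            core = m.direction * core
        elif m.trait == "sex":
            core = m.direction * (2.0 * sex - 1.0)
        else:
            raise ValueError(f"module {m.name}: unknown trait {m.trait!r}")
        e = _zscore(core + rng.normal(0.0, m.eigengene_noise_sd, size=n_samples))
        eigengenes[m.name] = e
        # loading that yields the target within-module correlation given the
        # NB + log-noise variance floor
        a0, a1 = cfg.dispersion
        noise_var = a0 + cfg.noise_sd**2  # approximate log-scale residual variance
        lam_base = np.sqrt(m.within_cor / (1.0 - m.within_cor) * noise_var)
        n_hub = max(1, int(round(m.hub_fraction * m.size)))
        for i in range(m.size):
            is_hub = i < n_hub
            lam = lam_base * (1.6 if is_hub else 1.0)
            log_mu[g] += lam * e
            add_gene(
                f"{m.name.upper()}{i:04d}", "module",
                direction="up" if m.direction > 0 else "down",
                module=m.name, hub=is_hub,
                ssign=m.direction if m.trait == "sex" else 0,
            )
            g += 1

    assert g == cfg.n_genes

    # ----- biotypes ------------------------------------------------------
    biotypes = np.where(
        rng.random(cfg.n_genes) < 0.75, "protein_coding",
        np.where(rng.random(cfg.n_genes) < 0.6, "lncRNA", "processed_pseudogene"),
    )
    # planted classes skew protein-coding, giving the biotype test signal
    planted = np.array([c != "background" for c in klass])
    biotypes[planted & (rng.random(cfg.n_genes) < 0.8)] = "protein_coding"
    biotype = pd.Series(biotypes, index=gene_ids, name="biotype")

    # ----- library sizes and counts -------------------------------------
    lib = np.exp(rng.normal(cfg.log_library_mean, cfg.log_library_sd, size=n_samples))
    shallow_idx = rng.choice(n_samples, size=cfg.n_shallow, replace=False)
    lib[shallow_idx] = cfg.shallow_depth * rng.uniform(0.6, 0.95, size=cfg.n_shallow)

    log_mu = log_mu + base[:, np.newaxis] + gamma[:, np.newaxis] * sex[np.newaxis, :]
    log_mu = log_mu + rng.normal(0.0, cfg.noise_sd, size=log_mu.shape)
    rel = np.exp(log_mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[np.newaxis, :]
    a0, a1 = cfg.dispersion
    counts = _nb_sample(rng, mu, a0, a1)

    # outliers: permute gene labels within the sample (depth preserved)
    candidates = np.setdiff1d(np.arange(n_samples), shallow_idx)
    outlier_idx = rng.choice(candidates, size=cfg.n_outlier, replace=False)
    for s in outlier_idx:
        counts[:, s] = rng.permutation(counts[:, s])

    # ----- gene sets -----------------------------------------------------
    sets: dict[str, tuple[str, set[str]]] = {}
    planted_terms = []
    hub_by_module = {
        m.name: [gid for gid, mod, h in zip(gene_ids, module_of, hub_flag) if mod == m.name and h]
        for m in cfg.modules
    }
    term_no = 0
    for m in cfg.modules:
        hubs = hub_by_module[m.name]
        n_hub_in = max(1, int(round(cfg.gmt.planted_hub_fraction * len(hubs))))
        chosen_hubs = list(rng.choice(hubs, size=n_hub_in, replace=False))
        fill_n = max(cfg.gmt.size_range[0], int(len(chosen_hubs) / cfg.gmt.planted_hub_fraction)) - len(chosen_hubs)
        others = [gid for gid in gene_ids if gid not in set(chosen_hubs)]
        fillers = list(rng.choice(others, size=fill_n, replace=False))
        tid = f"T{term_no:04d}"
        sets[tid] = (f"planted {m.name} response", set(chosen_hubs) | set(fillers))
        planted_terms.append(tid)
        term_no += 1
    while term_no < cfg.gmt.n_terms:
        size = int(rng.integers(cfg.gmt.size_range[0], cfg.gmt.size_range[1] + 1))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        sets[f"T{term_no:04d}"] = (f"random process {term_no}", members)
        term_no += 1

    # ----- assemble ------------------------------------------------------
    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=list(meta["sample_id"]),
        counts=counts,
        biotype=biotype,
    )
    st = SampleTable(meta)
    truth = TruthTables(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class": klass,
                "true_k": true_k,
                "true_breakpoints": true_bps,
                "true_direction": true_dir,
                "module": module_of,
                "hub": hub_flag,
                "sex_sign": sex_sign,
                "biotype": biotypes,
            }
        ),
        samples=pd.DataFrame(
            {
                "sample_id": list(meta["sample_id"]),
                "shallow": np.isin(np.arange(n_samples), shallow_idx),
                "outlier": np.isin(np.arange(n_samples), outlier_idx),
            }
        ),
        terms=pd.DataFrame(
            {
                "term_id": list(sets),
                "planted": [tid in planted_terms for tid in sets],
            }
        ),
    )
    return SimulatedDataset(
        counts=cm,
        samples=st,
        truth=truth,
        gene_sets=GeneSetCollection(sets=sets, source="simulated"),
    )


def null_expression(
    n_genes: int = 2000,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Pure-noise dataset: flat NB means, no trends, no modules, no outliers."""
    cfg = config or SimulationConfig()
    from dataclasses import replace

    null_cfg = replace(
        cfg,
        seed=seed,
        n_background=n_genes,
        trendy=TrendySpec(n_genes=0),
        modules=(),
        n_shallow=0,
        n_outlier=0,
    )
    return simulate_dataset(null_cfg)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in the TSV/GMT dialects the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "annotation": out / "annotation.tsv",
        "gmt": out / "gene_sets.gmt",
        "truth_genes": out / "truth_genes.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_terms": out / "truth_terms.tsv",
    }
    try:
        dataset.counts.write_tsv(paths["counts"])
        dataset.samples.table.drop(columns=["sex_code"]).to_csv(
            paths["metadata"], sep="\t", index=False
        )
        pd.DataFrame(
            {
                "gene_id": dataset.counts.gene_ids,
                "symbol": dataset.counts.gene_ids,
                "biotype": dataset.counts.biotype.to_numpy(),
            }
        ).to_csv(paths["annotation"], sep="\t", index=False)
        write_gmt(dataset.gene_sets, paths["gmt"])
        dataset.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        dataset.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        dataset.truth.terms.to_csv(paths["truth_terms"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    return paths
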