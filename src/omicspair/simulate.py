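"""Synthetic two-group multi-omics data with planted interactions.

Generates a negative-binomial gene count matrix, a log-normal
metabolite abundance matrix, a covariate table (two unbalanced
phenotype groups, pens, batches, ages, RIN, FCR) and a small pathway
library.  A chosen number of gene-metabolite pairs is "planted": the
metabolite's log abundance is rebuilt from the normalized gene with a
group-specific slope, so downstream recovery can be scored against the
returned truth.

The raw-abundance scale of untargeted platforms is not standardized;
the log-normal choice here is a stand-in, adequate because the pipeline
only ever models log abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import OmicsMatrix, PathwayLibrary, SampleTable
from .preprocess import normalize_counts

PLANTED_SET = "planted_metabolites"


@dataclass
class SimConfig:
    n_genes: int = 200
    n_metabolites: int = 50
    n_samples: int = 40
    group_sizes: tuple[int, int] = (12, 28)
    n_pens: int = 8
    n_batches: int = 2
    nb_dispersion: float = 0.1
    log_mean_range: tuple[float, float] = (np.log(5.0), np.log(2000.0))
    noise_sd: float = 0.3
    #: magnitude of nuisance structure; zero them for an exactly
    #: calibrated null (no omitted-covariate structure in the layers)
    gene_covariate_sd: float = 0.05
    batch_shift_sd: float = 0.2
    met_noise_sd: float = 0.5
    n_planted: int = 0
    delta_slope: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ConfigError(f"group sizes {self.group_sizes} must sum to n_samples={self.n_samples}")
        if min(self.group_sizes) < 3:
            raise ConfigError("each phenotype group needs at least 3 samples")
        if self.n_pens > self.n_samples:
            raise ConfigError("more pens than samples")
        if self.n_batches > self.n_samples:
            raise ConfigError("more batches than samples")
        if self.n_planted > self.n_genes * self.n_metabolites:
            raise ConfigError("cannot plant more pairs than the gene x metabolite grid")
        if self.n_planted > min(self.n_genes, self.n_metabolites):
            raise ConfigError("planted pairs use distinct genes and metabolites; "
                              "n_planted must not exceed min(n_genes, n_metabolites)")
        if self.nb_dispersion <= 0 or self.noise_sd < 0:
            raise ConfigError("dispersion must be positive and noise_sd non-negative")
        if not self.log_mean_range[0] < self.log_mean_range[1]:
            raise ConfigError("log_mean_range must be an increasing interval")


@dataclass
class SimTruth:
    pairs: list[tuple[str, str, float, float]]  # (gene_id, metabolite_id, beta2, beta4)
    enriched_set: str = PLANTED_SET

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_id", "metabolite_id", "beta2", "beta4"])


def _balanced_random(levels: list[str], n: int, rng: np.random.Generator) -> np.ndarray:
    reps = np.tile(levels, n // len(levels) + 1)[:n]
    return rng.permutation(reps)


def simulate_dataset(cfg: SimConfig) -> tuple[OmicsMatrix, OmicsMatrix, SampleTable,
                                              SimTruth, PathwayLibrary]:
    """Generate (counts, abundances, metadata, truth, pathway library).

    Deterministic given ``cfg.seed``: a single integer-seeded generator
    drives every draw, so two runs with the same config are identical.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n0, n1 = cfg.group_sizes
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    met_ids = [f"M{i + 1:04d}" for i in range(cfg.n_metabolites)]

    # --- metadata -----------------------------------------------------
    group = np.array(["group0"] * n0 + ["group1"] * n1)
    fe_group = _balanced_random(["high", "low"], n, rng)
    pen = _balanced_random([f"pen{i + 1}" for i in range(cfg.n_pens)], n, rng)
    batch = _balanced_random([f"batch{i + 1}" for i in range(cfg.n_batches)], n, rng)
    rin = rng.normal(8.0, 0.5, n)
    slaughter_age = rng.normal(150.0, 5.0, n)
    sampling_age = slaughter_age - rng.uniform(5.0, 15.0, n)
    fcr = rng.normal(2.5, 0.3, n)
    meta = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "breed": group,          # the unbalanced two-group phenotype
        "fe_group": fe_group,
        "pen": pen,
        "batch": batch,
        "rin": np.round(rin, 3),
        "slaughter_age_days": np.round(slaughter_age, 1),
        "sampling_age_days": np.round(sampling_age, 1),
        "fcr": np.round(fcr, 4),
    }))
    p = (group == "group1").astype(float)

    # --- gene counts: NB with mean mu, variance mu + mu^2 * dispersion
    log_mu = rng.uniform(*cfg.log_mean_range, cfg.n_genes)
    pen_eff = rng.normal(0.0, cfg.gene_covariate_sd, (cfg.n_genes, cfg.n_pens))
    pen_idx = np.array([int(x[3:]) - 1 for x in pen])
    age_coef = rng.normal(0.0, cfg.gene_covariate_sd / 2, cfg.n_genes)
    rin_coef = rng.normal(0.0, cfg.gene_covariate_sd / 2, cfg.n_genes)
    z_age = (slaughter_age - slaughter_age.mean()) / max(slaughter_age.std(), 1e-9)
    z_rin = (rin - rin.mean()) / max(rin.std(), 1e-9)
    log_mu_gs = (log_mu[:, None] + pen_eff[:, pen_idx]
                 + age_coef[:, None] * z_age[None, :]
                 + rin_coef[:, None] * z_rin[None, :])
    mu = np.exp(log_mu_gs)
    nb_n = 1.0 / cfg.nb_dispersion
    counts_vals = rng.negative_binomial(nb_n, nb_n / (nb_n + mu)).astype(float)
    counts = OmicsMatrix(gene_ids, sample_ids, counts_vals, "counts")

    # --- metabolite abundances: log-normal with a batch shift ---------
    base = rng.uniform(2.0, 4.0, cfg.n_metabolites)
    batch_shift = (rng.normal(0.0, cfg.batch_shift_sd, cfg.n_batches)
                   if cfg.batch_shift_sd > 0 else np.zeros(cfg.n_batches))
    batch_idx = np.array([int(x[5:]) - 1 for x in batch])
    log_m = (base[:, None] + batch_shift[batch_idx][None, :]
             + rng.normal(0.0, cfg.met_noise_sd, (cfg.n_metabolites, n)))

    # --- plant interactions into chosen metabolites -------------------
    truth_pairs: list[tuple[str, str, float, float]] = []
    if cfg.n_planted:
        planted_genes = rng.choice(cfg.n_genes, cfg.n_planted, replace=False)
        planted_mets = rng.choice(cfg.n_metabolites, cfg.n_planted, replace=False)
        normalized = normalize_counts(counts)
        for gi, mi in zip(planted_genes, planted_mets):
            g = normalized.values[gi]
            g_sd = g.std()
            if g_sd == 0:  # degenerate gene; plant carries no signal
                g_norm = np.zeros(n)
            else:
                g_norm = (g - g.mean()) / g_sd
            beta2 = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            beta4 = cfg.delta_slope * rng.choice([-1.0, 1.0])
            beta3 = 0.3
            log_m[mi] = (base[mi] + batch_shift[batch_idx]
                         + beta2 * g_norm + beta3 * p + beta4 * g_norm * p
                         + rng.normal(0.0, cfg.noise_sd, n))
            truth_pairs.append((gene_ids[gi], met_ids[mi], float(beta2), float(beta4)))
    abundances = OmicsMatrix(met_ids, sample_ids, np.exp(log_m), "raw_abundance")
    truth = SimTruth(truth_pairs)

    # --- pathway library: one set of planted metabolites + decoys -----
    sets: dict[str, list[str]] = {}
    planted_members = sorted(m for _, m, _, _ in truth_pairs)
    if planted_members:
        sets[PLANTED_SET] = planted_members
    n_decoys = 4
    for d in range(n_decoys):
        size = int(rng.integers(5, max(6, cfg.n_metabolites // 4) + 1))
        members = rng.choice(met_ids, min(size, cfg.n_metabolites), replace=False)
        sets[f"decoy_set_{d + 1}"] = sorted(members)
    library = PathwayLibrary(sets)

    return counts, abundances, meta, truth, library


def simulate_null(cfg: SimConfig) -> tuple[OmicsMatrix, OmicsMatrix, SampleTable,
                                           SimTruth, PathwayLibrary]:
    """Same generator with no planted pairs (type-I-error harness)."""
    return simulate_dataset(replace(cfg, n_planted=0))
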