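"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the pipeline's input surface:

* structured genotypes under the Balding-Nichols model, where subpopulation
  allele frequencies are Beta-distributed around an ancestral frequency with
  variance ``F * p * (1 - p)`` so that the expected per-site F_ST equals the
  ``F`` parameter;
* negative-binomial expression counts with a multiplicative genotype effect
  on a designated interferon-stimulated-gene (ISG) set;
* Poisson McDonald-Kreitman count tables with a chosen true adaptive
  fraction ``alpha``;
* unphased multi-SNP genotypes drawn from a known haplotype pool.

A single seed fans out to independent substreams via ``SeedSequence.spawn``,
so fixing the seed makes every output bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "ExpressionSimSpec",
    "MKSimSpec",
    "simulate_structured_genotypes",
    "simulate_expression",
    "simulate_mk_counts",
    "simulate_haplotype_genotypes",
]


@dataclass
class SimulationConfig:
    """Parameters for Balding-Nichols structured-genotype simulation."""

    n_populations: int = 5
    samples_per_population: int = 200
    n_sites: int = 2000
    target_fst: float = 0.1
    ancestral_maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.samples_per_population, self.n_sites) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.target_fst <= 0.95:
            raise ValueError("target_fst must be in [0, 0.95]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must be an ordered interval within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class ExpressionSimSpec:
    """Parameters for negative-binomial expression with a genotype effect.

    ``dispersion`` is the NB over-dispersion alpha: var = mu + alpha * mu^2.
    Gene baselines are log-normal around ``baseline_mean``. ISG genes in
    alternate-allele carriers (dosage >= 1) have their mean multiplied by
    ``2 ** genotype_effect_log2``.
    """

    n_genes: int = 1000
    isg_set: tuple = ()
    genotype_effect_log2: float = 0.0
    dispersion: float = 0.1
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.isg_set:
            raise ValueError("isg_set must be non-empty")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")

    def gene_ids(self) -> list:
        base = [f"G{i:05d}" for i in range(self.n_genes - len(self.isg_set))]
        return list(self.isg_set) + base


@dataclass
class MKSimSpec:
    """Poisson MK-count simulation with true adaptive fraction ``alpha_true``.

    Under neutrality Dn/Ds = Pn/Ps = ratio_ns; adaptive substitutions
    inflate Dn by 1/(1 - alpha_true), so alpha estimated from expected
    counts equals alpha_true.
    """

    n_genes: int = 500
    alpha_true: float = 0.0
    mean_ds: float = 10.0
    mean_ps: float = 10.0
    ratio_ns: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_true < 1.0:
            raise ValueError("alpha_true must be in [0, 1)")
        if self.mean_ds < 0 or self.mean_ps <= 0 or self.ratio_ns <= 0:
            raise ValueError("rates must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _rng_stream(seed: int, stream: int) -> np.random.Generator:
    # one substream per operation keeps draws uncoupled across generators
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_structured_genotypes(cfg: SimulationConfig):
    """Draw genotypes for ``n_populations`` demes under Balding-Nichols.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The genotype matrix and a truth table with the ancestral frequency
        and each subpopulation's realized allele frequency parameter.
    """
    rng = _rng_stream(cfg.seed, 0)
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_sites)
    F = cfg.target_fst
    if F == 0.0:
        p_sub = np.tile(p_anc, (cfg.n_populations, 1))
    else:
        # Beta with mean p and variance F p (1-p): a = p(1-F)/F, b = (1-p)(1-F)/F
        scale = (1.0 - F) / F
        p_sub = rng.beta(p_anc * scale, (1.0 - p_anc) * scale,
                         size=(cfg.n_populations, cfg.n_sites))
    n = cfg.samples_per_population
    dosages = np.concatenate(
        [rng.binomial(2, p_sub[k], size=(n, cfg.n_sites)) for k in range(cfg.n_populations)],
        axis=0,
    )
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, MISSING, dosages)

    pops = [f"POP{k}" for k in range(cfg.n_populations)]
    labels = np.repeat(pops, n)
    sample_ids = [f"{pop}_S{i:04d}" for pop in pops for i in range(n)]
    site_ids = [f"rs{j:06d}" for j in range(cfg.n_sites)]
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, cfg.n_sites + 1) * 100,
            "ref": "A",
            "alt": "G",
            "gene": [f"GENE{j // 10:05d}" for j in range(cfg.n_sites)],
            "consequence": "missense_variant",
        },
        index=pd.Index(site_ids, name="site_id"),
    )[SITE_COLUMNS]
    truth = pd.DataFrame(
        {"ancestral_freq": p_anc, **{pop: p_sub[k] for k, pop in enumerate(pops)}},
        index=sites.index,
    )
    return GenotypeMatrix(sample_ids, labels, sites, dosages), truth


def simulate_expression(genotypes_at_snp, spec: ExpressionSimSpec):
    """Simulate a genes x samples NB count matrix keyed to one SNP's dosages.

    Samples with dosage >= 1 form the carrier group; ISG-set genes in
    carriers get a ``2 ** genotype_effect_log2`` mean shift.

    Returns
    -------
    (DataFrame, ndarray)
        Count matrix (genes x samples) and a boolean carrier mask.
    """
    dosages = np.asarray(genotypes_at_snp)
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    rng = _rng_stream(spec.seed, 1)
    genes = spec.gene_ids()
    missing = set(spec.isg_set) - set(genes)
    if missing:
        raise ValueError(f"isg_set members outside gene universe: {sorted(missing)}")
    n_samples = dosages.size
    baselines = spec.baseline_mean * rng.lognormal(0.0, 0.5, size=len(genes))
    mu = np.tile(baselines[:, None], (1, n_samples))
    carrier = dosages >= 1
    isg_rows = np.isin(genes, list(spec.isg_set))
    mu[np.ix_(isg_rows, carrier)] *= 2.0 ** spec.genotype_effect_log2
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=genes,
                      columns=[f"CL{i:04d}" for i in range(n_samples)])
    return df, carrier


def simulate_mk_counts(spec: MKSimSpec) -> pd.DataFrame:
    """Per-gene Poisson Pn/Ps/Dn/Ds counts under ``alpha_true``."""
    rng = _rng_stream(spec.seed, 2)
    n = spec.n_genes
    ds = rng.poisson(spec.mean_ds, size=n)
    ps = rng.poisson(spec.mean_ps, size=n)
    pn = rng.poisson(spec.ratio_ns * spec.mean_ps, size=n)
    dn = rng.poisson(spec.ratio_ns * spec.mean_ds / (1.0 - spec.alpha_true), size=n)
    return pd.DataFrame(
        {"Pn": pn, "Ps": ps, "Dn": dn, "Ds": ds},
        index=pd.Index([f"GENE{i:05d}" for i in range(n)], name="gene"),
    )


def simulate_haplotype_genotypes(hap_freqs, n_samples: int, seed: int = 0,
                                 population_labels=None) -> GenotypeMatrix:
    """Draw unphased genotypes from a known haplotype pool.

    Parameters
    ----------
    hap_freqs
        Mapping of haplotype string (e.g. ``"0101"``, one 0/1 allele per
        SNP) to frequency; frequencies must be non-negative and sum to 1.
    n_samples
        Number of diploid individuals; each receives two i.i.d. haplotypes.
    """
    haps = list(hap_freqs)
    freqs = np.asarray([hap_freqs[h] for h in haps], dtype=float)
    if (freqs < 0).any():
        raise ValueError("haplotype frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    k = len(haps[0])
    if any(len(h) != k for h in haps):
        raise ValueError("haplotype strings must share one length")
    alleles = np.array([[int(c) for c in h] for h in haps])  # (H, k)
    rng = _rng_stream(seed, 3)
    draws = rng.choice(len(haps), size=(n_samples, 2), p=freqs / freqs.sum())
    dosages = alleles[draws[:, 0]] + alleles[draws[:, 1]]
    if population_labels is None:
        population_labels = np.array(["pop0"] * n_samples)
    sites = pd.DataFrame(
        {
            "chrom": "5",
            "pos": np.arange(1, k + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "gene": "LOCUS",
            "consequence": "missense_variant",
        },
        index=pd.Index([f"snp{j}" for j in range(k)], name="site_id"),
    )[SITE_COLUMNS]
    return GenotypeMatrix(
        [f"IND{i:04d}" for i in range(n_samples)],
        np.asarray(population_labels), sites, dosages,
    )
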