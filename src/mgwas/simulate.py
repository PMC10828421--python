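"""Synthetic genotype-microbiome-trait cohort generator.

The generator reproduces the statistical structure the analysis pipeline
assumes, with a truth table for parameter-recovery tests:

* genotypes from a two-subpopulation Balding-Nichols model — per variant an
  ancestral frequency p ~ Uniform(maf_range) and subpopulation frequencies
  ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so Hardy-Weinberg holds within
  subpopulation by construction;
* compositional taxon abundances from a two-part (hurdle) model: a latent
  log10 abundance carrying planted additive SNP effects (AB channel),
  covariate terms, a subpopulation shift and Gaussian noise, zeroed through a
  presence hurdle whose log-odds carry the planted PA-channel effects, then
  closed so every sample sums to one.  Core taxa (first ~20%) have presence
  probability 0.995 and the rest span 15-90%, giving both >95% and 10-95%
  realized prevalences;
* host traits with taxon -> trait causal effects per unit log10 abundance,
  confounded by a shared latent N(0,1) variable that loads on both the
  taxon's latent abundance and the trait, so naive regression is biased while
  the planted SNPs remain valid instruments (no direct SNP -> trait path).

All distributional choices are synthetic stand-ins chosen to be realistic for
a shotgun-metagenomics cohort; none are estimated from real data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import AbundanceTable, GenotypeMatrix, write_vcf, write_abundance

# covariate loadings on the latent log10 abundance (per SD of the covariate)
_COV_LOADING = 0.05
_SUBPOP_SHIFT_SD = 0.25
_CORE_FRACTION = 0.2
_CORE_PI = 0.995


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    effect_table rows are (variant_index, taxon_index, effect_size, channel)
    with channel "AB" (per-allele shift of latent log10 abundance) or "PA"
    (per-allele shift of presence log-odds).  causal_table rows are
    (taxon_index, trait_index, causal_effect_per_log10, confounder_loading_on
    _taxon, confounder_loading_on_trait).
    """

    n_samples: int = 200
    n_variants: int = 100
    n_taxa: int = 20
    n_traits: int = 2
    fst: float = 0.01
    maf_range: tuple = (0.05, 0.5)
    subpop_fractions: tuple = (0.5, 0.5)
    effect_table: list = dataclasses.field(default_factory=list)
    causal_table: list = dataclasses.field(default_factory=list)
    noise_sd: float = 1.0
    trait_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if abs(sum(self.subpop_fractions) - 1.0) > 1e-9:
            raise ValueError("subpop_fractions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for v, t, _, ch in self.effect_table:
            if not (0 <= v < self.n_variants and 0 <= t < self.n_taxa):
                raise ValueError(f"effect ({v},{t}) out of range")
            if ch not in ("AB", "PA"):
                raise ValueError(f"channel must be AB or PA, got {ch!r}")
        for t, tr, *_ in self.causal_table:
            if not (0 <= t < self.n_taxa and 0 <= tr < self.n_traits):
                raise ValueError(f"causal ({t},{tr}) out of range")


@dataclasses.dataclass
class SimTruth:
    planted_effects: pd.DataFrame
    causal_effects: pd.DataFrame
    subpop_labels: np.ndarray


@dataclasses.dataclass
class Cohort:
    genotypes: GenotypeMatrix
    subpop_labels: np.ndarray
    covariates: pd.DataFrame
    abundance: AbundanceTable
    traits: pd.DataFrame
    truth: SimTruth


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def beta_for_standardized(target: float, maf: float, noise_sd: float) -> float:
    """Per-allele effect giving a standardized effect ``target`` at a given MAF."""
    return target * noise_sd / np.sqrt(2.0 * maf * (1.0 - maf))


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols genotypes; returns (GenotypeMatrix with stats, labels)."""
    rng = _rng(config.seed, 1)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    n0 = int(round(n * config.subpop_fractions[0]))
    labels = rng.permutation(np.array([0] * n0 + [1] * (n - n0)))
    if config.fst > 0:
        c = (1.0 - config.fst) / config.fst
        sub_freq = rng.beta(p_anc * c, (1.0 - p_anc) * c, size=(2, m))
    else:
        sub_freq = np.vstack([p_anc, p_anc])
    dosages = rng.binomial(2, sub_freq[labels, :]).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_000 * (np.arange(m) + 1),
            "id": [f"var{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i:05d}" for i in range(n)]
    g = GenotypeMatrix(samples, variants, dosages).compute_stats()
    return g, labels


def simulate_covariates(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Host covariates: age ~ N(30,5), sex ~ Bern(0.63), BMI ~ N(22,3), reads ~ LogNormal."""
    rng = _rng(seed, 2)
    df = pd.DataFrame(
        {
            "age": rng.normal(30.0, 5.0, n_samples),
            "sex": rng.binomial(1, 0.63, n_samples).astype(float),
            "bmi": rng.normal(22.0, 3.0, n_samples),
            "read_count": rng.lognormal(np.log(2.5e8), 0.3, n_samples),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n_samples)], name="sample_id"),
    )
    return df


def _confounders(config: SimConfig, n: int) -> np.ndarray:
    """Shared latent confounders, one N(0,1) column per causal_table row.

    Derived from the config seed so the microbiome and trait generators see
    the identical draw.
    """
    rng = _rng(config.seed, 5)
    return rng.standard_normal((n, max(len(config.causal_table), 1)))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_microbiome(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimConfig,
    subpop_labels: np.ndarray | None = None,
) -> AbundanceTable:
    """Hurdle-model compositional abundances with planted SNP effects."""
    if list(map(str, genotypes.samples)) != list(map(str, covariates.index)):
        raise KeyError("genotype and covariate sample IDs do not match")
    rng = _rng(config.seed, 3)
    n, t = genotypes.n_samples, config.n_taxa
    dos = genotypes.imputed().dosages
    core = max(1, int(round(_CORE_FRACTION * t)))
    pi = np.concatenate([np.full(core, _CORE_PI), rng.uniform(0.15, 0.9, t - core)])
    mu = rng.normal(-2.0, 1.0, t)
    latent = np.tile(mu, (n, 1))
    latent += _COV_LOADING * _zscore(covariates["age"].to_numpy())[:, None]
    latent += _COV_LOADING * _zscore(covariates["bmi"].to_numpy())[:, None]
    if subpop_labels is not None:
        shift = rng.normal(0.0, _SUBPOP_SHIFT_SD, t)
        latent += np.asarray(subpop_labels)[:, None] * shift
    logits = np.tile(np.log(pi / (1.0 - pi)), (n, 1))
    for v, tx, beta, channel in config.effect_table:
        if channel == "AB":
            latent[:, tx] += beta * dos[:, v]
        else:
            latent[:, tx] += 0.0
            logits[:, tx] += beta * (dos[:, v] - dos[:, v].mean())
    U = _confounders(config, n)
    for k, (tx, _, _, load_taxon, _) in enumerate(config.causal_table):
        latent[:, tx] += load_taxon * U[:, k]
    latent += rng.normal(0.0, config.noise_sd, size=(n, t))
    present = rng.random((n, t)) < 1.0 / (1.0 + np.exp(-logits))
    empty = ~present.any(axis=1)
    if empty.any():  # keep every sample non-empty for closure
        present[np.where(empty)[0], np.argmax(latent[empty], axis=1)] = True
    raw = np.where(present, 10.0**latent, 0.0)
    closed = raw / raw.sum(axis=1, keepdims=True)
    names = [f"k__Bacteria|g__Genus{j}|s__Species{j}" for j in range(t)]
    values = pd.DataFrame(closed, index=covariates.index.copy(), columns=names)
    return AbundanceTable(values)


def simulate_traits(
    abundance: AbundanceTable,
    covariates: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    subpop_labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Host traits with confounded taxon -> trait causal effects.

    The trait is alpha * log10(taxon abundance, half-minimum pseudocount for
    zeros) + confounder loading * U + covariate terms + N(0, trait_noise_sd).
    """
    from .assoc import half_min_pseudocount

    rng = _rng(config.seed if seed is None else seed, 4)
    n = abundance.n_samples
    traits = np.zeros((n, config.n_traits))
    traits += _COV_LOADING * _zscore(covariates["age"].to_numpy())[:, None]
    traits += _COV_LOADING * covariates["sex"].to_numpy()[:, None]
    U = _confounders(config, n)
    values = abundance.values.to_numpy()
    for k, (tx, tr, alpha, _, load_trait) in enumerate(config.causal_table):
        if alpha != 0.0:
            col = values[:, tx]
            floored = np.maximum(col, half_min_pseudocount(col))
            traits[:, tr] += alpha * np.log10(floored)
        traits[:, tr] += load_trait * U[:, k]
    traits += rng.normal(0.0, config.trait_noise_sd, size=traits.shape)
    trait_df = pd.DataFrame(
        traits,
        index=abundance.values.index.copy(),
        columns=[f"trait{j}" for j in range(config.n_traits)],
    )
    planted = pd.DataFrame(
        [
            {
                "variant_index": v,
                "variant_id": f"var{v}",
                "taxon_index": t,
                "taxon": abundance.features[t],
                "effect": b,
                "channel": ch,
                "effect_allele": "ALT",
            }
            for v, t, b, ch in config.effect_table
        ],
        columns=["variant_index", "variant_id", "taxon_index", "taxon",
                 "effect", "channel", "effect_allele"],
    )
    causal = pd.DataFrame(
        [
            {
                "taxon_index": t,
                "taxon": abundance.features[t],
                "trait_index": tr,
                "trait": f"trait{tr}",
                "alpha": a,
                "load_taxon": lt,
                "load_trait": ltr,
            }
            for t, tr, a, lt, ltr in config.causal_table
        ],
        columns=["taxon_index", "taxon", "trait_index", "trait", "alpha",
                 "load_taxon", "load_trait"],
    )
    labels = (np.asarray(subpop_labels) if subpop_labels is not None
              else np.zeros(n, dtype=int))
    return trait_df, SimTruth(planted, causal, labels)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort: genotypes, covariates, abundances, traits, truth."""
    genotypes, labels = simulate_genotypes(config)
    covariates = simulate_covariates(config.n_samples, seed=config.seed)
    abundance = simulate_microbiome(genotypes, covariates, config, subpop_labels=labels)
    traits, truth = simulate_traits(abundance, covariates, config, subpop_labels=labels)
    return Cohort(genotypes, labels, covariates, abundance, traits, truth)


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write genotypes.vcf, abundance.tsv, covariates.tsv, traits.tsv, truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.vcf",
        "abundance": outdir / "abundance.tsv",
        "covariates": outdir / "covariates.tsv",
        "traits": outdir / "traits.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(cohort.genotypes, paths["genotypes"])
    write_abundance(cohort.abundance, paths["abundance"])
    cohort.covariates.to_csv(paths["covariates"], sep="\t")
    cohort.traits.to_csv(paths["traits"], sep="\t")
    truth = pd.concat(
        [
            cohort.truth.planted_effects.assign(kind="planted_effect"),
            cohort.truth.causal_effects.assign(kind="causal_effect"),
        ],
        ignore_index=True,
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
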