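"""Synthetic data with the statistical structure the diet analysis assumes.

Generates every input the pipeline consumes: mock-community read counts
distorted by per-species amplification offsets, field faecal-sample count
tables whose true compositions carry month / population / pod structure,
replicate pairs, and diploid SNP genotypes with missingness and allele
error.  Ground truth is returned alongside each dataset so downstream
stages can be validated end to end.

The seasonal structure is deliberately smooth: known prey species carry
ecology-motivated peak months (Chinook-type spring/summer peaks giving way
to coho in late summer and chum in autumn, with groundfish in winter), so
trend-recovery checks have a recoverable signal.  Species the generator
does not recognise receive seeded random phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from orcadiet.calibration import MockDesign
from orcadiet.errors import InvalidCompositionError, InvalidDesignError
from orcadiet.mocks import GENERAL_CONTROL, MOCK_SPECIES, SALMONID_CONTROL

__all__ = [
    "GenotypeConfig",
    "SimConfig",
    "SimTruth",
    "sim_efficiencies",
    "distort_proportions",
    "sim_reads",
    "sim_mock_dataset",
    "sim_field_dataset",
    "sim_genotypes",
]

# baseline diet weights: Chinook-dominated with chum/coho secondary,
# matching the broad prey ranking reported for resident killer whales
_BASE_DIET: dict[str, float] = {
    "chinook": 0.45,
    "chum": 0.18,
    "coho": 0.10,
    "halibut": 0.06,
    "lingcod": 0.05,
    "herring": 0.04,
    "sockeye": 0.04,
    "pink": 0.03,
    "rainbow_trout": 0.03,
    "atlantic_salmon": 0.02,
}

# month of peak abundance in the diet (1-12); smooth cosine seasonality
_PEAK_MONTH: dict[str, float] = {
    "chinook": 5.0,
    "chum": 10.5,
    "coho": 9.0,
    "halibut": 7.0,
    "lingcod": 1.5,
    "herring": 2.5,
    "sockeye": 7.5,
    "pink": 8.0,
    "rainbow_trout": 1.0,
    "atlantic_salmon": 6.0,
}

_PODS = {"A": ("J", "K", "L"), "B": ("AB", "AD16", "AK")}


@dataclass
class GenotypeConfig:
    """Design of the SNP genotyping panel and its noise processes."""

    n_individuals: int = 20
    n_loci: int = 68
    missing_rate: float = 0.05
    error_rate: float = 0.01
    samples_per_individual: int = 3
    known_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidDesignError("n_individuals must be >= 1")
        if self.n_loci < 1:
            raise InvalidDesignError("n_loci must be >= 1")
        for name in ("missing_rate", "error_rate", "known_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidDesignError(f"{name} must be in [0, 1], got {v}")
        if self.samples_per_individual < 1:
            raise InvalidDesignError("samples_per_individual must be >= 1")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults mirror the study layout: ten mock species across two controls
    with five replicates each, 185 field samples from two populations at an
    expected depth of 150,000 reads (the order of the mean post-QC library
    size), amplification offsets with spread 0.3, and a 68-locus SNP panel.
    """

    n_species: int = len(MOCK_SPECIES)
    n_mock_replicates_per_control: int = 5
    reads_per_sample: int = 150_000
    alpha_sd: float = 0.3
    n_field_samples: int = 185
    n_replicate_pairs: int = 5
    month_effect_size: float = 1.0
    population_effect_size: float = 0.25
    pod_effect_size: float = 0.25
    overdispersion: float = 0.0
    dirichlet_concentration: float = 5.0
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_species",
            "n_mock_replicates_per_control",
            "reads_per_sample",
            "n_field_samples",
        ):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1")
        if self.n_species < 2:
            raise InvalidDesignError("need >= 2 species")
        for name in (
            "alpha_sd",
            "month_effect_size",
            "population_effect_size",
            "pod_effect_size",
            "overdispersion",
        ):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        if self.n_replicate_pairs < 0:
            raise InvalidDesignError("n_replicate_pairs must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise InvalidDesignError("dirichlet_concentration must be > 0")

    @property
    def species(self) -> list[str]:
        """Species IDs: the mock species first, padded with extras if needed."""
        base = list(MOCK_SPECIES)
        if self.n_species <= len(base):
            return base[: self.n_species]
        extras = [f"other_{i:02d}" for i in range(1, self.n_species - len(base) + 1)]
        return base + extras


@dataclass
class SimTruth:
    """Ground truth for a simulated field dataset."""

    true_alpha: dict[str, float]
    true_proportions: pd.DataFrame
    true_individual: pd.Series
    reference_species: str

    def __post_init__(self) -> None:
        sums = self.true_proportions.sum(axis=1)
        if (np.abs(sums - 1.0) > 1e-9).any():
            raise InvalidCompositionError("true proportions must sum to 1 per sample")
        if self.true_alpha.get(self.reference_species, None) != 0.0:
            raise InvalidDesignError("reference species offset must be exactly 0")


def sim_efficiencies(
    species: Sequence[str],
    alpha_sd: float,
    seed: int,
    reference: str | None = None,
) -> dict[str, float]:
    """Draw per-species log amplification offsets.

    Offsets are drawn Normal(0, ``alpha_sd``); the reference species
    (alphabetically first by default) is set exactly to 0.
    """
    species = list(species)
    if len(species) < 2:
        raise InvalidDesignError("need >= 2 species for an efficiency design")
    if alpha_sd < 0:
        raise InvalidDesignError("alpha_sd must be >= 0")
    reference = reference if reference is not None else sorted(species)[0]
    if reference not in species:
        raise InvalidDesignError(f"reference {reference!r} not among species")
    rng = np.random.default_rng(seed)
    alpha = {s: float(rng.normal(0.0, alpha_sd)) for s in species}
    alpha[reference] = 0.0
    return alpha


def distort_proportions(
    true_props: pd.Series | Mapping[str, float],
    alpha: Mapping[str, float],
) -> pd.Series:
    """Expected observed proportions under multiplicative amplification bias.

    ``theta_i = p_i exp(alpha_i) / sum_k p_k exp(alpha_k)`` — the noiseless
    forward model the calibration step inverts.
    """
    p = pd.Series(true_props, dtype=float)
    if (p < 0).any():
        raise InvalidCompositionError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InvalidCompositionError(f"proportions must sum to 1, got {p.sum():.6f}")
    a = np.array([alpha.get(s, 0.0) for s in p.index])
    w = p.values * np.exp(a)
    return pd.Series(w / w.sum(), index=p.index)


def sim_reads(
    true_props: pd.Series | Mapping[str, float],
    alpha: Mapping[str, float],
    depth: int,
    overdispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Simulate one sample's read counts under the distortion model.

    Counts are Multinomial(depth, theta) at the distorted proportions, or
    Dirichlet-multinomial with precision ``overdispersion`` when positive.
    The returned vector always sums exactly to ``depth``.
    """
    if depth < 1:
        raise InvalidDesignError("depth must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    theta = distort_proportions(true_props, alpha)
    probs = theta.values
    if overdispersion > 0:
        # Dirichlet draw only over species with positive expected proportion
        pos = probs > 0
        sampled = rng.dirichlet(overdispersion * probs[pos])
        probs = np.zeros_like(probs)
        probs[pos] = sampled
    counts = rng.multinomial(int(depth), probs)
    return pd.Series(counts, index=theta.index)


def sim_mock_dataset(
    alpha: Mapping[str, float],
    n_replicates: int = 5,
    depth: int = 150_000,
    overdispersion: float = 0.0,
    seed: int = 0,
    controls: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, MockDesign]:
    """Simulate mock-community replicates under known offsets.

    Returns the mock sample × species count table (zero-filled for species
    absent from a control) and the matching :class:`MockDesign`.
    """
    controls = controls or {"general": GENERAL_CONTROL, "salmonid": SALMONID_CONTROL}
    design = MockDesign.from_controls(controls, n_replicates=n_replicates)
    rng = np.random.default_rng(seed)
    species = sorted(design.species)
    rows = {}
    for sample_id, control in design.replicates.items():
        known = design.proportions.loc[control].reindex(species, fill_value=0.0)
        rows[sample_id] = sim_reads(known, alpha, depth, overdispersion, rng)
    counts = pd.DataFrame(rows).T.reindex(columns=species).astype(int)
    counts.index.name = "sample_id"
    return counts, design


def _seasonal_phase(species: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [
            _PEAK_MONTH[s] if s in _PEAK_MONTH else rng.uniform(1.0, 12.0)
            for s in species
        ]
    )


def sim_field_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the field faecal-sample dataset.

    Returns ``(counts, metadata, truth)``: a sample × species count table,
    per-sample metadata (population ∈ {A, B}, pod, individual, month, year,
    date, replicate_group), and the ground truth (true offsets, true
    compositions, true individual per sample).

    Population A is sampled year-round; population B only May–September,
    mirroring the seasonal coverage asymmetry of opportunistic field
    collection.  Mean compositions shift smoothly with month (cosine around
    each species' peak month) and by population and pod according to the
    configured effect sizes; per-sample compositions are Dirichlet around
    those means.  The final ``n_replicate_pairs`` samples are replicates of
    existing samples: they share the donor's true composition, individual
    and date (alternating technical / biological replicate labelling).
    """
    species = config.species
    ss = np.random.SeedSequence(config.seed)
    s_alpha, s_traits, s_layout, s_comp, s_counts = ss.spawn(5)

    alpha = sim_efficiencies(
        species, config.alpha_sd, np.random.default_rng(s_alpha).integers(2**31 - 1)
    )
    reference = sorted(species)[0]

    rng_t = np.random.default_rng(s_traits)
    peak = _seasonal_phase(species, rng_t)
    pop_dir = rng_t.normal(0.0, 1.0, size=len(species))
    pod_dir = {
        pod: rng_t.normal(0.0, 1.0, size=len(species))
        for pops in _PODS.values()
        for pod in pops
    }
    base_w = np.array([_BASE_DIET.get(s, 0.02) for s in species])
    log_base = np.log(base_w / base_w.sum())

    rng_l = np.random.default_rng(s_layout)
    n_ind = config.genotype.n_individuals
    individuals = [f"W{i:03d}" for i in range(1, n_ind + 1)]
    ind_pop = {
        ind: ("A" if i < (n_ind + 1) // 2 else "B")
        for i, ind in enumerate(individuals)
    }
    ind_pod = {
        ind: _PODS[ind_pop[ind]][rng_l.integers(len(_PODS[ind_pop[ind]]))]
        for ind in individuals
    }
    pop_individuals = {
        p: [i for i in individuals if ind_pop[i] == p] for p in ("A", "B")
    }
    if not pop_individuals["A"] or not pop_individuals["B"]:
        raise InvalidDesignError("need individuals in both populations")

    rng_c = np.random.default_rng(s_comp)
    rng_r = np.random.default_rng(s_counts)

    records = []
    true_props = {}
    for k in range(config.n_field_samples):
        sample_id = f"S{k + 1:04d}"
        pop = "A" if rng_l.random() < 0.5 else "B"
        ind = pop_individuals[pop][rng_l.integers(len(pop_individuals[pop]))]
        pod = ind_pod[ind]
        month = int(rng_l.integers(1, 13)) if pop == "A" else int(rng_l.integers(5, 10))
        year = int(rng_l.integers(2011, 2022))
        day = int(rng_l.integers(1, 29))
        date = f"{year:04d}-{month:02d}-{day:02d}"

        eta = (
            log_base
            + config.month_effect_size * np.cos(2 * np.pi * (month - peak) / 12.0)
            + config.population_effect_size * (0.5 if pop == "A" else -0.5) * pop_dir
            + config.pod_effect_size * pod_dir[pod]
        )
        mean = np.exp(eta - eta.max())
        mean /= mean.sum()
        props = rng_c.dirichlet(config.dirichlet_concentration * mean)
        # Dirichlet can underflow to exact 0; keep compositions strictly valid
        props = np.clip(props, 1e-12, None)
        props /= props.sum()
        true_props[sample_id] = props
        records.append(
            {
                "sample_id": sample_id,
                "population": pop,
                "pod": pod,
                "individual": ind,
                "month": month,
                "year": year,
                "date": date,
                "replicate_group": "",
            }
        )

    # replicate pairs: re-sequence existing samples (same truth, new counts)
    donors = rng_l.choice(
        config.n_field_samples,
        size=min(config.n_replicate_pairs, config.n_field_samples),
        replace=False,
    )
    for j, donor_idx in enumerate(sorted(donors)):
        donor = records[donor_idx]
        sample_id = f"{donor['sample_id']}R2"
        rec = dict(donor, sample_id=sample_id)
        if j % 2 == 0:  # technical replicate: declared subdivision of one sample
            group = f"tech_{donor['sample_id']}"
            rec["replicate_group"] = group
            records[donor_idx]["replicate_group"] = group
        records.append(rec)
        true_props[sample_id] = true_props[donor["sample_id"]]

    metadata = pd.DataFrame(records).set_index("sample_id")
    props_df = pd.DataFrame.from_dict(true_props, orient="index", columns=species)
    props_df = props_df.loc[metadata.index]
    props_df.index.name = "sample_id"

    counts = {}
    for sample_id in metadata.index:
        depth = max(1, int(rng_r.poisson(config.reads_per_sample)))
        counts[sample_id] = sim_reads(
            props_df.loc[sample_id], alpha, depth, config.overdispersion, rng_r
        )
    counts_df = pd.DataFrame(counts).T.reindex(columns=species).astype(int)
    counts_df.index.name = "sample_id"

    truth = SimTruth(
        true_alpha=alpha,
        true_proportions=props_df,
        true_individual=metadata["individual"].copy(),
        reference_species=reference,
    )
    return counts_df, metadata, truth


def sim_genotypes(
    config: SimConfig,
    sample_to_individual: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate diploid SNP genotypes for faecal samples.

    Each individual carries a fixed genotype (Hardy–Weinberg draws at
    per-locus allele frequencies ~ Uniform(0.1, 0.9)).  Each sample copies
    its individual's genotype with per-allele error ``error_rate`` and
    per-locus missingness ``missing_rate``.  Calls are coded 0/1/2 (count of
    the alternate allele) with −1 for missing.

    Returns ``(matrix, reference_db, truth)``: the sample × locus call
    matrix, a reference database of error-free genotypes for the "known"
    subset of individuals, and the sample → individual truth mapping.

    When ``sample_to_individual`` is given (e.g. from a simulated field
    dataset), one genotype row is generated per listed sample; otherwise
    ``samples_per_individual`` samples are generated per individual.
    """
    g = config.genotype
    ss = np.random.SeedSequence(config.seed + 1_000_003)
    rng = np.random.default_rng(ss)

    loci = [f"locus_{j:03d}" for j in range(1, g.n_loci + 1)]
    if sample_to_individual is None:
        individuals = [f"W{i:03d}" for i in range(1, g.n_individuals + 1)]
        mapping = {}
        for ind in individuals:
            for r in range(1, g.samples_per_individual + 1):
                mapping[f"{ind}_s{r}"] = ind
        truth = pd.Series(mapping, name="individual")
    else:
        truth = pd.Series(sample_to_individual, name="individual").astype(str)
        individuals = sorted(truth.unique())
    truth.index.name = "sample_id"

    freqs = rng.uniform(0.1, 0.9, size=g.n_loci)
    geno = {ind: rng.binomial(2, freqs) for ind in individuals}

    calls = np.empty((len(truth), g.n_loci), dtype=np.int8)
    for row, (sample, ind) in enumerate(truth.items()):
        gt = geno[ind]
        a1 = (gt >= 1).astype(np.int8)
        a2 = (gt == 2).astype(np.int8)
        flip1 = rng.random(g.n_loci) < g.error_rate
        flip2 = rng.random(g.n_loci) < g.error_rate
        obs = np.where(flip1, 1 - a1, a1) + np.where(flip2, 1 - a2, a2)
        obs = obs.astype(np.int8)
        obs[rng.random(g.n_loci) < g.missing_rate] = -1
        calls[row] = obs
    matrix = pd.DataFrame(calls, index=truth.index, columns=loci)

    n_known = int(round(g.known_fraction * len(individuals)))
    known = sorted(rng.choice(individuals, size=n_known, replace=False))
    reference_db = pd.DataFrame(
        {ind: geno[ind] for ind in known}, index=loci
    ).T.astype(np.int8)
    reference_db.index.name = "individual"
    return matrix, reference_db, truth
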