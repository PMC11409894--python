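"""Mock-community calibration of species-specific amplification bias.

PCR amplifies template DNA of different species with different efficiencies,
so the read proportions observed in an amplicon library are a multiplicatively
distorted version of the true template composition.  With mock communities of
known composition sequenced alongside the field samples, the distortion is
identifiable: if a sample's true composition is ``p`` and species *i* carries
a log-efficiency offset ``alpha_i`` (relative to a reference species whose
offset is fixed at 0), the expected observed proportion is

    theta_i = p_i * exp(alpha_i) / sum_k p_k * exp(alpha_k)

Observed mock read counts are modelled as Multinomial(depth, theta) and the
offsets are given a hierarchical prior, alpha_i ~ Normal(0, tau) with
tau ~ half-Normal(1), pooling information across species.  The posterior is
sampled with emcee's affine-invariant ensemble sampler, run as several
independent ensembles ("chains") so that potential-scale-reduction
diagnostics are meaningful.  Field samples are then corrected by inverting
the distortion at the posterior estimates:  p_hat_i ∝ r_i * exp(-alpha_i).

Species never present in a mock community cannot be calibrated; they pass
through with alpha = 0 (uncorrected), which matches how minor, uncalibrated
diet species are handled in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

from orcadiet.errors import (
    EmptySampleError,
    InvalidDesignError,
    UnknownSpeciesError,
)

__all__ = [
    "MockDesign",
    "SamplerSettings",
    "EfficiencyEstimates",
    "CalibratedSample",
    "fit_efficiencies",
    "calibrate_sample",
    "convergence_report",
]

RHAT_WARN = 1.05
ESS_WARN = 100.0


@dataclass
class MockDesign:
    """Known composition of each mock control and the replicate layout.

    Parameters
    ----------
    proportions
        DataFrame indexed by control ID with one column per species; each row
        holds the pre-determined input proportions of that control and must
        sum to 1 (±1e-6).
    replicates
        Series mapping mock sample ID -> control ID, one entry per sequenced
        mock replicate.
    """

    proportions: pd.DataFrame
    replicates: pd.Series

    def __post_init__(self) -> None:
        self.proportions = self.proportions.astype(float).fillna(0.0)
        sums = self.proportions.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise InvalidDesignError(
                f"control proportions must sum to 1: {bad.to_dict()}"
            )
        n_present = (self.proportions > 0).sum(axis=1)
        if (n_present < 2).any():
            raise InvalidDesignError("each control needs >=2 species")
        unknown = set(self.replicates) - set(self.proportions.index)
        if unknown:
            raise InvalidDesignError(f"replicates reference unknown controls: {unknown}")

    @classmethod
    def from_controls(
        cls,
        controls: Mapping[str, Mapping[str, float]],
        n_replicates: int = 5,
    ) -> "MockDesign":
        """Build a design with ``n_replicates`` technical replicates per control."""
        species = sorted({s for c in controls.values() for s in c})
        props = pd.DataFrame(
            [[controls[c].get(s, 0.0) for s in species] for c in controls],
            index=list(controls),
            columns=species,
        )
        reps = {}
        for c in controls:
            for r in range(1, n_replicates + 1):
                reps[f"mock_{c}_r{r}"] = c
        return cls(props, pd.Series(reps, name="control"))

    @property
    def species(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class SamplerSettings:
    """MCMC settings for the efficiency fit.

    Defaults follow the calibration protocol of three chains of 10,000
    iterations including a 5,000-iteration warm-up; ``max_tree_depth`` is
    recorded for provenance but has no effect on the ensemble sampler.
    """

    chains: int = 3
    iterations: int = 10_000
    warmup: int = 5_000
    n_walkers: int = 32
    thin: int = 5
    max_tree_depth: int = 12

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.chains < 1 or self.n_walkers < 4:
            raise ValueError("need >=1 chain and >=4 walkers")


@dataclass
class EfficiencyEstimates:
    """Posterior summaries of per-species amplification offsets (alpha).

    ``summary`` has one row per species with posterior mean, sd, central 95%
    interval, potential-scale-reduction (rhat) and bulk effective sample size;
    the reference species row is degenerate at 0 with no diagnostics.
    ``draws`` holds pooled posterior draws (n_draws × n_species) with the
    reference column identically 0, enabling full posterior propagation
    through the correction step.
    """

    summary: pd.DataFrame
    reference: str
    draws: np.ndarray
    tau_summary: dict
    settings: dict

    @property
    def species(self) -> list[str]:
        return list(self.summary.index)

    @property
    def alpha(self) -> pd.Series:
        """Posterior-mean offset per species (reference exactly 0)."""
        return self.summary["mean"]

    def __post_init__(self) -> None:
        ref = self.summary.loc[self.reference]
        if not (ref[["mean", "sd", "lo95", "hi95"]] == 0).all():
            raise InvalidDesignError("reference species interval must be degenerate at 0")


@dataclass
class CalibratedSample:
    """Calibrated composition of one sample after bias inversion."""

    sample_id: str
    proportions: pd.Series
    corrected_counts: pd.Series
    total_reads: float
    intervals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-6:
            raise ValueError("calibrated proportions must sum to 1")


def _log_prob_factory(Y: np.ndarray, P: np.ndarray, ref_idx: int):
    """Vectorised log-posterior over walker batches.

    Parameters are ``[alpha_free (K-1), log_tau]``; the reference alpha is
    pinned at 0.  Multinomial constants are dropped.
    """
    n_species = P.shape[1]
    free_idx = [i for i in range(n_species) if i != ref_idx]

    def log_prob(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        W = params.shape[0]
        alpha = np.zeros((W, n_species))
        alpha[:, free_idx] = params[:, :-1]
        log_tau = params[:, -1]
        tau = np.exp(log_tau)

        # prior: tau ~ half-Normal(1) with log-Jacobian of the log transform,
        # alpha_free | tau ~ Normal(0, tau)
        lp = stats.halfnorm.logpdf(tau, scale=1.0) + log_tau
        lp += stats.norm.logpdf(params[:, :-1], loc=0.0, scale=tau[:, None]).sum(axis=1)

        T = P[None, :, :] * np.exp(alpha)[:, None, :]
        T /= T.sum(axis=2, keepdims=True)
        lp += xlogy(Y[None, :, :], T).sum(axis=(1, 2))
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    return log_prob


def fit_efficiencies(
    mock_counts: pd.DataFrame,
    design: MockDesign,
    settings: SamplerSettings | None = None,
    reference: str | None = None,
    seed: int = 0,
) -> EfficiencyEstimates:
    """Fit per-species amplification offsets to mock-community read counts.

    Parameters
    ----------
    mock_counts
        Sample × species read counts for the mock replicates; every row index
        must appear in ``design.replicates`` and every column in the design's
        species set.
    design
        Known control compositions and the replicate → control mapping.
    settings
        MCMC settings; defaults to :class:`SamplerSettings`.
    reference
        Species whose offset is pinned at 0; defaults to the alphabetically
        first mock species.
    seed
        Seed for walker initialisation and proposal randomness; each chain
        derives an independent stream.

    Returns
    -------
    EfficiencyEstimates with posterior summaries, pooled draws and
    convergence diagnostics.  Emits a ``UserWarning`` (never fails) when any
    potential-scale-reduction exceeds 1.05.
    """
    import arviz as az
    import emcee

    settings = settings or SamplerSettings()
    species = sorted(design.species)
    extra = set(mock_counts.columns) - set(species)
    if extra:
        raise UnknownSpeciesError(
            f"count species absent from mock design: {sorted(extra)}"
        )
    missing_samples = set(mock_counts.index) - set(design.replicates.index)
    if missing_samples:
        raise InvalidDesignError(
            f"mock samples not in design replicate map: {sorted(missing_samples)}"
        )
    Y = mock_counts.reindex(columns=species, fill_value=0).astype(float)
    if (Y.values < 0).any():
        raise ValueError("read counts must be non-negative")
    zero = Y.sum(axis=1) == 0
    if zero.any():
        raise EmptySampleError(f"all-zero mock samples: {list(Y.index[zero])}")

    reference = reference if reference is not None else species[0]
    if reference not in species:
        raise InvalidDesignError(f"reference {reference!r} not a mock species")
    ref_idx = species.index(reference)
    controls = design.replicates.loc[Y.index]
    P = design.proportions.reindex(columns=species, fill_value=0.0).loc[controls].values

    log_prob = _log_prob_factory(Y.values, P, ref_idx)
    ndim = len(species)  # K-1 alphas + log_tau
    n_keep = (settings.iterations - settings.warmup) // settings.thin

    ss = np.random.SeedSequence(seed)
    chain_draws = []
    for chain_seed in ss.spawn(settings.chains):
        rng = np.random.default_rng(chain_seed)
        p0 = np.column_stack(
            [
                rng.normal(0.0, 0.5, size=(settings.n_walkers, ndim - 1)),
                rng.normal(0.0, 0.5, size=(settings.n_walkers, 1)),
            ]
        )
        sampler = emcee.EnsembleSampler(
            settings.n_walkers, ndim, log_prob, vectorize=True
        )
        state = np.random.RandomState(rng.integers(2**31 - 1))
        sampler.random_state = state.get_state()
        sampler.run_mcmc(p0, settings.iterations, progress=False)
        chain = sampler.get_chain(discard=settings.warmup, thin=settings.thin)
        # walker-major flattening: each chain is one ensemble's pooled history
        chain_draws.append(np.moveaxis(chain, 1, 0).reshape(-1, ndim))

    draws = np.stack(chain_draws)  # (chains, n_keep*n_walkers, ndim)
    free_species = [s for s in species if s != reference]
    ds = az.from_dict(
        posterior={
            "alpha": draws[:, :, :-1],
            "log_tau": draws[:, :, -1],
        },
        coords={"species": free_species},
        dims={"alpha": ["species"]},
    )
    rhat = az.rhat(ds)
    ess = az.ess(ds)

    pooled = draws.reshape(-1, ndim)
    alpha_draws = np.zeros((pooled.shape[0], len(species)))
    free_idx = [i for i in range(len(species)) if i != ref_idx]
    alpha_draws[:, free_idx] = pooled[:, :-1]

    summary = pd.DataFrame(
        {
            "mean": alpha_draws.mean(axis=0),
            "sd": alpha_draws.std(axis=0, ddof=1),
            "lo95": np.percentile(alpha_draws, 2.5, axis=0),
            "hi95": np.percentile(alpha_draws, 97.5, axis=0),
        },
        index=pd.Index(species, name="species"),
    )
    summary.loc[reference] = 0.0
    summary["rhat"] = np.nan
    summary["ess"] = np.nan
    summary.loc[free_species, "rhat"] = rhat["alpha"].values
    summary.loc[free_species, "ess"] = ess["alpha"].values

    tau_draws = np.exp(pooled[:, -1])
    tau_summary = {
        "mean": float(tau_draws.mean()),
        "sd": float(tau_draws.std(ddof=1)),
        "lo95": float(np.percentile(tau_draws, 2.5)),
        "hi95": float(np.percentile(tau_draws, 97.5)),
        "rhat": float(rhat["log_tau"].values),
        "ess": float(ess["log_tau"].values),
    }

    worst = np.nanmax(summary["rhat"].values)
    if max(worst, tau_summary["rhat"]) > RHAT_WARN:
        warnings.warn(
            f"potential-scale-reduction above {RHAT_WARN} (max {worst:.3f}); "
            "increase iterations",
            UserWarning,
            stacklevel=2,
        )

    record = asdict(settings)
    record.update({"seed": seed, "reference": reference, "n_keep_per_chain": n_keep})
    return EfficiencyEstimates(
        summary=summary,
        reference=reference,
        draws=alpha_draws,
        tau_summary=tau_summary,
        settings=record,
    )


def calibrate_sample(
    counts: pd.Series | Mapping[str, float],
    estimates: EfficiencyEstimates,
    mode: str = "posterior_mean",
    sample_id: str = "",
) -> CalibratedSample:
    """Invert amplification bias for one sample's read-count vector.

    Calibrated proportions are ``p_hat_i ∝ r_i * exp(-alpha_i)``.  Species
    without an efficiency estimate pass through uncorrected (alpha = 0).
    ``mode="draws"`` propagates the pooled posterior draws and attaches a
    central 95% interval per species; the point proportions are then the
    posterior-mean compositions.
    """
    counts = pd.Series(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise EmptySampleError(f"sample {sample_id!r} has zero total reads")
    if mode not in ("posterior_mean", "draws"):
        raise ValueError(f"unknown mode {mode!r}")

    alpha = estimates.alpha.reindex(counts.index).fillna(0.0)
    intervals = None
    if mode == "posterior_mean":
        w = counts.values * np.exp(-alpha.values)
        props = w / w.sum()
    else:
        n_draws = estimates.draws.shape[0]
        A = np.zeros((n_draws, len(counts)))
        present = [i for i, s in enumerate(counts.index) if s in estimates.species]
        cols = [estimates.species.index(counts.index[i]) for i in present]
        A[:, present] = estimates.draws[:, cols]
        W = counts.values[None, :] * np.exp(-A)
        Pd = W / W.sum(axis=1, keepdims=True)
        props = Pd.mean(axis=0)
        intervals = pd.DataFrame(
            {
                "lo95": np.percentile(Pd, 2.5, axis=0),
                "hi95": np.percentile(Pd, 97.5, axis=0),
            },
            index=counts.index,
        )

    props = pd.Series(props, index=counts.index, name=sample_id or None)
    return CalibratedSample(
        sample_id=sample_id,
        proportions=props,
        corrected_counts=props * total,
        total_reads=float(total),
        intervals=intervals,
    )


def calibrate_table(
    counts: pd.DataFrame,
    estimates: EfficiencyEstimates,
    mode: str = "posterior_mean",
) -> pd.DataFrame:
    """Calibrate every row of a sample × species count table.

    Returns corrected read counts (row sums preserved); divide by row totals
    for calibrated proportions.  Zero-total rows are dropped with a warning.
    """
    zero = counts.sum(axis=1) <= 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} zero-read sample(s): "
            f"{list(counts.index[zero])}",
            UserWarning,
            stacklevel=2,
        )
        counts = counts.loc[~zero]
    rows = [
        calibrate_sample(counts.loc[s], estimates, mode=mode, sample_id=str(s)).corrected_counts
        for s in counts.index
    ]
    return pd.DataFrame(rows, index=counts.index)


def convergence_report(estimates: EfficiencyEstimates) -> pd.DataFrame:
    """Per-free-alpha diagnostic table with a pass/warn flag.

    A row warns when rhat exceeds 1.05 or bulk effective sample size falls
    below 100 draws.
    """
    free = estimates.summary.drop(index=estimates.reference)
    report = free[["mean", "sd", "lo95", "hi95", "rhat", "ess"]].copy()
    warn = (report["rhat"] > RHAT_WARN) | (report["ess"] < ESS_WARN)
    report["flag"] = np.where(warn, "warn", "pass")
    return report
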