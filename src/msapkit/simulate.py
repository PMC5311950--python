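"""Synthetic MSAP datasets with known ground truth.

Emulates the statistical structure of two-enzyme MSAP band matrices from
K populations: a fraction of loci are methylation-susceptible (MSL) with
per-population latent methylation probabilities drawn around population
means mu_k (Beta-distributed locus effects, so per-locus diversity varies
as in real data); the remaining loci are non-methylated (NML) whose band
frequencies diverge across populations under a Balding-Nichols-style
F-model, giving a tunable PhiST target.  Latent states are rendered to
HPA/MSP band pairs through the scoring truth table; sporadic scoring
errors flip band bits independently and extra Type IV calls model
hypermethylation/null alleles.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BandMatrixPair, MsapError, SampleSheet
from .scoring import StateMatrix, states_to_bands


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror a two-population MSAP study.

    n_populations, sizes, n_loci
        K populations of ``sizes[k]`` individuals over ``n_loci`` loci.
    msl_fraction
        Fraction of loci that are methylation-susceptible (default 0.53,
        the typical MSL share of anonymous CCGG AFLP loci in marine
        invertebrates).
    methylation_means
        mu_k in (0,1) per population: expected proportion of methylated
        (Type II/III) calls at MSL loci.
    beta_concentration
        Concentration of the Beta(mu*c, (1-mu)*c) locus-effect draws.
    divergence_f
        F in [0,1) of the NML band-frequency model: ancestral frequency
        p ~ Uniform(0.1, 0.9), population frequencies
        Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 means identical frequencies.
    scoring_error_rate
        Per-band independent bit-flip probability.
    type_iv_extra_rate
        Probability a latent MSL state is replaced by Type IV
        (hypermethylation / restriction-site mutation).
    """

    n_populations: int = 2
    sizes: tuple[int, ...] = (30, 30)
    n_loci: int = 380
    msl_fraction: float = 0.53
    methylation_means: tuple[float, ...] = (0.55, 0.67)
    beta_concentration: float = 10.0
    divergence_f: float = 0.1
    scoring_error_rate: float = 0.0
    type_iv_extra_rate: float = 0.25
    nml_ancestral_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0
    population_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1 or len(self.sizes) != self.n_populations:
            raise MsapError("sizes must list one entry per population")
        if len(self.methylation_means) != self.n_populations:
            raise MsapError("methylation_means must list one entry per population")
        if any(not 0 < m < 1 for m in self.methylation_means):
            raise MsapError("methylation means must lie strictly in (0, 1)")
        if not 0 <= self.divergence_f < 1:
            raise MsapError("divergence_f must lie in [0, 1)")
        for name in ("msl_fraction", "scoring_error_rate", "type_iv_extra_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise MsapError(f"{name} must lie in [0, 1)")
        if self.beta_concentration <= 0:
            raise MsapError("beta_concentration must be positive")
        lo, hi = self.nml_ancestral_range
        if not 0 < lo < hi < 1:
            raise MsapError("nml_ancestral_range must satisfy 0 < lo < hi < 1")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.population_labels is not None:
            return self.population_labels
        return tuple(f"pop{k + 1}" for k in range(self.n_populations))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (pre-error latent values)."""

    latent_states: StateMatrix
    is_msl: np.ndarray                       # per-locus ground truth
    methylation_probs: np.ndarray            # populations x MSL loci
    nml_band_freqs: np.ndarray               # populations x NML loci
    realized_methylation: dict[str, float]   # per-population latent (II+III)/(I+II+III)
    config: SimulationConfig

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "is_msl": self.is_msl.astype(int).tolist(),
            "realized_methylation": self.realized_methylation,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[BandMatrixPair, SampleSheet, SimulationTruth]:
    """Draw one MSAP dataset with known ground truth.

    MSL loci: per locus and population, a methylation probability is
    drawn from Beta centered on mu_k; each individual is methylated with
    that probability (the methylated state split uniformly between
    Type II and Type III), otherwise Type I; Type IV replaces the latent
    state at ``type_iv_extra_rate``.  NML loci: per-population band
    frequencies from the F-model; band present -> Type I, absent ->
    Type IV.  States are rendered to HPA/MSP bands via the truth table
    and scoring errors flip band bits independently.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_populations
    L = config.n_loci
    n_msl = int(round(L * config.msl_fraction))
    n_nml = L - n_msl
    n_total = int(sum(config.sizes))
    labels = config.labels

    pop_of = np.repeat(np.arange(K), config.sizes)
    populations = np.array([labels[k] for k in pop_of], dtype=object)
    individuals = []
    for k, size in enumerate(config.sizes):
        individuals.extend(f"{labels[k]}_{i + 1:02d}" for i in range(size))

    is_msl = np.zeros(L, dtype=bool)
    is_msl[:n_msl] = True  # MSL first; locus order carries no signal
    loci = [f"{'MSL' if is_msl[j] else 'NML'}_{j + 1:03d}" for j in range(L)]

    states = np.empty((n_total, L), dtype=np.int8)

    # MSL loci: Beta locus effects around mu_k, then Bernoulli methylation
    c = config.beta_concentration
    mu = np.asarray(config.methylation_means)
    meth_probs = rng.beta(mu[:, None] * c, (1 - mu[:, None]) * c, size=(K, n_msl))
    if n_msl:
        p_ind = meth_probs[pop_of]                       # individuals x MSL loci
        methylated = rng.random((n_total, n_msl)) < p_ind
        ii_or_iii = np.where(rng.random((n_total, n_msl)) < 0.5, 2, 3)
        states[:, is_msl] = np.where(methylated, ii_or_iii, 1)
        if config.type_iv_extra_rate > 0:
            drop = rng.random((n_total, n_msl)) < config.type_iv_extra_rate
            msl_block = states[:, is_msl]
            msl_block[drop] = 4
            states[:, is_msl] = msl_block

    # NML loci: F-model band frequencies; band -> Type I, no band -> Type IV
    F = config.divergence_f
    lo, hi = config.nml_ancestral_range
    ancestral = rng.uniform(lo, hi, size=n_nml)
    if n_nml:
        if F > 0:
            a = ancestral * (1 - F) / F
            b = (1 - ancestral) * (1 - F) / F
            band_freqs = rng.beta(a[None, :], b[None, :], size=(K, n_nml))
        else:
            band_freqs = np.broadcast_to(ancestral, (K, n_nml)).copy()
        f_ind = band_freqs[pop_of]
        band = rng.random((n_total, n_nml)) < f_ind
        states[:, ~is_msl] = np.where(band, 1, 4)
    else:
        band_freqs = np.zeros((K, 0))

    latent = StateMatrix(
        individuals=list(individuals),
        loci=loci,
        states=states.copy(),
        populations=populations,
    )

    realized = {}
    for k, lab in enumerate(labels):
        sub = states[pop_of == k][:, is_msl]
        scorable = np.isin(sub, (1, 2, 3)).sum()
        meth = np.isin(sub, (2, 3)).sum()
        realized[lab] = float(meth / scorable) if scorable else float("nan")

    hpa, msp = states_to_bands(states)
    if config.scoring_error_rate > 0:
        hpa = hpa ^ (rng.random(hpa.shape) < config.scoring_error_rate)
        msp = msp ^ (rng.random(msp.shape) < config.scoring_error_rate)

    pair = BandMatrixPair(
        loci=loci,
        individuals=list(individuals),
        hpa=hpa.astype(np.int8),
        msp=msp.astype(np.int8),
    )
    sheet = SampleSheet(populations=dict(zip(individuals, populations)))
    truth = SimulationTruth(
        latent_states=latent,
        is_msl=is_msl,
        methylation_probs=meth_probs,
        nml_band_freqs=np.asarray(band_freqs),
        realized_methylation=realized,
        config=config,
    )
    return pair, sheet, truth


def _nml_phist(config: SimulationConfig, seed: int) -> float:
    """PhiST point estimate on the NML partition of one simulated dataset."""
    from .differentiation import _amova_components, _phi, pairwise_distance
    from .scoring import ScoringConfig, binarize_nml, classify_loci, classify_states

    cfg = dataclasses.replace(config, seed=seed)
    pair, sheet, _ = simulate_dataset(cfg)
    states = classify_states(pair, populations=sheet.groups(pair.individuals))
    classes = classify_loci(states, ScoringConfig())
    mat, _ = binarize_nml(states, classes)
    dist = pairwise_distance(mat, ids=list(pair.individuals))
    groups = sheet.groups(pair.individuals)
    _, codes = np.unique(groups, return_inverse=True)
    _, _, s2a, s2w, _ = _amova_components(dist.values, codes, codes.max() + 1)
    return _phi(s2a, s2w)


def null_rejection_rate(
    n_replicates: int = 500,
    alpha: float = 0.05,
    n_perm: int = 199,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> float:
    """Empirical size of the PhiST permutation test under the exchangeable null.

    Simulates ``n_replicates`` datasets with zero divergence (F = 0,
    equal methylation means), runs the NML AMOVA permutation test on
    each, and returns the fraction of replicates with p <= ``alpha``.  A
    well-calibrated test at alpha = 0.05 should reject in roughly 5% of
    replicates.
    """
    from .differentiation import amova, pairwise_distance
    from .scoring import ScoringConfig, binarize_nml, classify_loci, classify_states

    base = config or SimulationConfig(
        n_loci=100,
        sizes=(15, 15),
        methylation_means=(0.6, 0.6),
        divergence_f=0.0,
    )
    if base.divergence_f != 0:
        raise MsapError("null calibration requires divergence_f = 0")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    rejections = 0
    for r in range(n_replicates):
        cfg = dataclasses.replace(base, seed=int(seeds[2 * r] % (2**31)))
        pair, sheet, _ = simulate_dataset(cfg)
        states = classify_states(pair, populations=sheet.groups(pair.individuals))
        classes = classify_loci(states, ScoringConfig())
        mat, _ = binarize_nml(states, classes)
        dist = pairwise_distance(mat, ids=list(pair.individuals))
        res = amova(
            dist,
            sheet.groups(pair.individuals),
            n_perm=n_perm,
            seed=int(seeds[2 * r + 1] % (2**31)),
        )
        rejections += res.p_value <= alpha
    return rejections / n_replicates


def calibrate_phist(
    f_values: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    n_replicates: int = 50,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean realized NML PhiST as a function of the divergence parameter F.

    Runs the full simulate -> score -> classify -> AMOVA chain per
    replicate, so the curve reflects what the estimator recovers (scoring
    error and the polymorphism filter included), not the raw model.
    Returns a DataFrame (divergence_f, mean_phi_st, sd_phi_st,
    n_replicates), monotone non-decreasing in F in expectation.
    """
    base = config or SimulationConfig(
        n_loci=120,
        sizes=(20, 20),
        methylation_means=(0.6, 0.6),
        seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, f in enumerate(f_values):
        seeds = np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(n_replicates)
        phis = [
            _nml_phist(dataclasses.replace(base, divergence_f=float(f)), int(s % (2**31)))
            for s in seeds
        ]
        rows.append(
            {
                "divergence_f": float(f),
                "mean_phi_st": float(np.mean(phis)),
                "sd_phi_st": float(np.std(phis, ddof=1)),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
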