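"""Methylation-state scoring of paired HpaII/MspI band profiles.

Both isoschizomers cut unmethylated CCGG.  HpaII is blocked by internal-C
methylation, MspI by external-C (hemi)methylation, and both are blocked by
hypermethylation or by sequence change at the restriction target.  The
joint band pattern of the two digests therefore encodes a four-state
methylation call per individual and locus:

    ===========  ==========  =======================================
    HpaII band   MspI band   state
    ===========  ==========  =======================================
    1            1           Type I   — unmethylated
    0            1           Type II  — internal-C methylation
    1            0           Type III — external-C / hemimethylation
    0            0           Type IV  — hypermethylation or mutation
    ===========  ==========  =======================================

Loci whose fraction of methylated calls (Types II+III) across all samples
exceeds an error-rate threshold (ERT) are methylation-susceptible loci
(MSL, epigenetic signal); the rest are non-methylated loci (NML, genetic
signal: their band pattern varies only through sequence change).  Type IV
is ambiguous (hypermethylation vs mutation) and is treated as missing
data in MSL analyses by default.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BandMatrixPair, EmptyAnalysisError, MsapFormatError


class MethylationState(enum.IntEnum):
    """Four-state methylation call from the two-enzyme truth table."""

    TYPE_I = 1    # both enzymes cut: unmethylated
    TYPE_II = 2   # HpaII blocked, MspI cuts: internal-C methylation
    TYPE_III = 3  # HpaII cuts, MspI blocked: external-C / hemimethylation
    TYPE_IV = 4   # neither cuts: hypermethylation or restriction-site mutation


STATE_TOKENS = {1: "I", 2: "II", 3: "III", 4: "IV"}


@dataclass
class StateMatrix:
    """Individuals x loci methylation states with population labels."""

    individuals: list[str]
    loci: list[str]
    states: np.ndarray  # int8 codes 1..4
    populations: np.ndarray  # object array aligned with individuals

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.states.shape != (len(self.individuals), len(self.loci)):
            raise MsapFormatError("state matrix shape does not match labels")
        if len(self.populations) != len(self.individuals):
            raise MsapFormatError("population labels do not match individuals")
        if not np.isin(self.states, (1, 2, 3, 4)).all():
            raise MsapFormatError("state codes must be in {1,2,3,4}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, mask: np.ndarray) -> "StateMatrix":
        """New StateMatrix restricted to the loci selected by ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        return StateMatrix(
            individuals=list(self.individuals),
            loci=[l for l, k in zip(self.loci, mask) if k],
            states=self.states[:, mask],
            populations=self.populations,
        )

    def to_frame(self) -> pd.DataFrame:
        """States as I/II/III/IV tokens with population/individual index."""
        tokens = np.vectorize(STATE_TOKENS.get)(self.states)
        return pd.DataFrame(
            tokens,
            index=pd.MultiIndex.from_arrays(
                [self.populations, self.individuals], names=["population", "individual"]
            ),
            columns=self.loci,
        )


class TypeIVPolicy(str, enum.Enum):
    MISSING = "missing"
    UNMETHYLATED = "unmethylated-state"


class NMLPresence(str, enum.Enum):
    NOT_TYPE_IV = "not-typeiv"   # any cut indicates the restriction site exists
    TYPE_I_ONLY = "typei-only"


@dataclass(frozen=True)
class ScoringConfig:
    """Locus classification and binarization settings.

    ert
        Error-rate threshold separating genuine methylation polymorphism
        from scoring error; a locus is MSL iff its proportion of
        methylated (Type II/III) calls across all samples is strictly
        greater than ``ert``.  Default 0.05.
    type_iv_policy
        How Type IV (uninterpretable) cells enter MSL methylation
        matrices: ``missing`` (default) or ``unmethylated-state``.
    nml_presence
        Band-presence convention at NML loci: ``not-typeiv`` (default;
        a band in either digest counts as presence) or ``typei-only``.
    """

    ert: float = 0.05
    type_iv_policy: TypeIVPolicy = TypeIVPolicy.MISSING
    nml_presence: NMLPresence = NMLPresence.NOT_TYPE_IV

    def __post_init__(self) -> None:
        if not 0 <= self.ert < 1:
            raise ValueError("ert must lie in [0, 1)")
        object.__setattr__(self, "type_iv_policy", TypeIVPolicy(self.type_iv_policy))
        object.__setattr__(self, "nml_presence", NMLPresence(self.nml_presence))


@dataclass
class LocusClassification:
    """Per-locus MSL/NML call, discordance proportion and polymorphism flag.

    ``label`` is ``MSL``/``NML`` before the polymorphism filter;
    ``retained`` marks loci passing the filter; the effective class of a
    non-retained locus is ``excluded``.
    """

    loci: list[str]
    is_msl: np.ndarray          # bool
    discordance: np.ndarray     # proportion of Type II+III calls per locus
    polymorphic: np.ndarray     # bool, per the >=2-of-each-state filter

    @property
    def classes(self) -> np.ndarray:
        out = np.where(self.is_msl, "MSL", "NML").astype(object)
        out[~self.polymorphic] = "excluded"
        return out

    @property
    def n_msl(self) -> int:
        return int(self.is_msl.sum())

    @property
    def n_nml(self) -> int:
        return int((~self.is_msl).sum())

    @property
    def n_msl_polymorphic(self) -> int:
        return int((self.is_msl & self.polymorphic).sum())

    @property
    def n_nml_polymorphic(self) -> int:
        return int((~self.is_msl & self.polymorphic).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "label": np.where(self.is_msl, "MSL", "NML"),
                "discordance": self.discordance,
                "polymorphic": self.polymorphic,
                "class": self.classes,
            }
        )


@dataclass
class MethylationLevel:
    """Global methylation level: (Type II + III) / (Type I + II + III).

    ``individual_levels`` carries per-individual state counts and the
    proportion (NaN-flagged when an individual has zero scorable loci).
    ``population_levels`` reports, per population, both the pooled-count
    proportion and the mean of individual proportions — the two
    conventions differ and are kept distinct.
    """

    individual_levels: pd.DataFrame
    population_levels: pd.DataFrame


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def classify_states(pair: BandMatrixPair, populations: np.ndarray | None = None) -> StateMatrix:
    """Map paired band profiles to the four-state methylation matrix.

    Truth table: (hpa, msp) = (1,1) -> Type I, (0,1) -> Type II,
    (1,0) -> Type III, (0,0) -> Type IV.
    """
    if pair.hpa.shape != pair.msp.shape:
        raise MsapFormatError("hpa/msp shape mismatch")
    states = (1 + (1 - pair.hpa) + 2 * (1 - pair.msp)).astype(np.int8)
    if populations is None:
        populations = np.array(["pop0"] * pair.n_individuals, dtype=object)
    return StateMatrix(
        individuals=list(pair.individuals),
        loci=list(pair.loci),
        states=states,
        populations=np.asarray(populations, dtype=object),
    )


def states_to_bands(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of the truth table: state codes -> (hpa, msp) 0/1 arrays."""
    s = np.asarray(states)
    hpa = np.isin(s, (MethylationState.TYPE_I, MethylationState.TYPE_III)).astype(np.int8)
    msp = np.isin(s, (MethylationState.TYPE_I, MethylationState.TYPE_II)).astype(np.int8)
    return hpa, msp


def polymorphism_filter(matrix: np.ndarray, min_count: int = 2) -> np.ndarray:
    """Columns retained iff both states occur >= ``min_count`` times.

    ``matrix`` is a float array of 0/1 with NaN for missing; counts are
    over non-missing entries only.  Returns a boolean column mask.
    """
    m = np.asarray(matrix, dtype=float)
    ones = np.nansum(m == 1, axis=0)
    zeros = np.nansum(m == 0, axis=0)
    return (ones >= min_count) & (zeros >= min_count)


def _msl_binary(states: np.ndarray, policy: TypeIVPolicy) -> np.ndarray:
    out = np.full(states.shape, np.nan)
    out[states == MethylationState.TYPE_I] = 0.0
    out[(states == MethylationState.TYPE_II) | (states == MethylationState.TYPE_III)] = 1.0
    if policy is TypeIVPolicy.UNMETHYLATED:
        out[states == MethylationState.TYPE_IV] = 0.0
    return out


def _nml_binary(states: np.ndarray, presence: NMLPresence) -> np.ndarray:
    if presence is NMLPresence.TYPE_I_ONLY:
        return (states == MethylationState.TYPE_I).astype(float)
    return (states != MethylationState.TYPE_IV).astype(float)


def classify_loci(states: StateMatrix, config: ScoringConfig | None = None) -> LocusClassification:
    """Partition loci into MSL/NML by the error-rate threshold.

    The discordance proportion of a locus is the count of methylated
    (Type II/III) calls over all individuals (Type IV rows included in
    the denominator).  A locus is MSL iff that proportion strictly
    exceeds ``config.ert``.  The polymorphism filter (>=2 occurrences of
    each state in the locus's downstream binary encoding) sets the
    ``polymorphic`` flag; failing loci are excluded downstream.
    """
    config = config or ScoringConfig()
    if states.n_individuals < 2:
        raise MsapFormatError("locus classification needs at least 2 individuals")
    s = states.states
    methylated = (s == MethylationState.TYPE_II) | (s == MethylationState.TYPE_III)
    discordance = methylated.mean(axis=0)
    is_msl = discordance > config.ert

    msl_mat = _msl_binary(s, config.type_iv_policy)
    nml_mat = _nml_binary(s, config.nml_presence)
    poly_msl = polymorphism_filter(msl_mat)
    poly_nml = polymorphism_filter(nml_mat)
    polymorphic = np.where(is_msl, poly_msl, poly_nml)
    return LocusClassification(
        loci=list(states.loci),
        is_msl=is_msl,
        discordance=discordance,
        polymorphic=polymorphic,
    )


def binarize_msl(
    states: StateMatrix,
    classes: LocusClassification,
    config: ScoringConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Binary methylation matrix over retained MSL loci.

    Entries: Type II/III -> 1 (methylated), Type I -> 0, Type IV ->
    NaN under the default ``missing`` policy (0 under
    ``unmethylated-state``).  Returns the float matrix and locus labels.
    """
    config = config or ScoringConfig()
    keep = classes.is_msl & classes.polymorphic
    if not keep.any():
        raise EmptyAnalysisError("no polymorphic MSL loci survive filtering")
    mat = _msl_binary(states.states[:, keep], config.type_iv_policy)
    loci = [l for l, k in zip(states.loci, keep) if k]
    return mat, loci


def binarize_nml(
    states: StateMatrix,
    classes: LocusClassification,
    config: ScoringConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Binary band-presence matrix over retained NML loci.

    Presence defaults to "not Type IV": at a locus whose discordance is
    sub-threshold noise, a band in either digest shows the restriction
    site exists, so absence (Type IV) is the genetic signal.
    """
    config = config or ScoringConfig()
    keep = ~classes.is_msl & classes.polymorphic
    if not keep.any():
        raise EmptyAnalysisError("no polymorphic NML loci survive filtering")
    mat = _nml_binary(states.states[:, keep], config.nml_presence)
    loci = [l for l, k in zip(states.loci, keep) if k]
    return mat, loci


def methylation_level(states: StateMatrix) -> MethylationLevel:
    """Global methylation level per individual and per population.

    The proportion (#II + #III) / (#I + #II + #III) ignores Type IV,
    whose methylation status cannot be specified.  Individuals with zero
    scorable loci get NaN and a warning; population aggregates report
    both the pooled-count proportion and the mean of individual
    proportions.
    """
    s = states.states
    counts = {
        t: (s == code).sum(axis=1)
        for t, code in (("I", 1), ("II", 2), ("III", 3), ("IV", 4))
    }
    num = counts["II"] + counts["III"]
    den = counts["I"] + counts["II"] + counts["III"]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    if (den == 0).any():
        bad = [states.individuals[i] for i in np.flatnonzero(den == 0)]
        warnings.warn(f"individuals with zero scorable loci: {bad}", stacklevel=2)

    ind = pd.DataFrame(
        {
            "individual": states.individuals,
            "population": states.populations,
            "n_type_i": counts["I"],
            "n_type_ii": counts["II"],
            "n_type_iii": counts["III"],
            "n_type_iv": counts["IV"],
            "proportion": prop,
        }
    )
    pop_rows = []
    for pop, sub in ind.groupby("population", sort=False):
        pooled_num = int((sub["n_type_ii"] + sub["n_type_iii"]).sum())
        pooled_den = int((sub["n_type_i"] + sub["n_type_ii"] + sub["n_type_iii"]).sum())
        pop_rows.append(
            {
                "population": pop,
                "n_individuals": len(sub),
                "pooled_proportion": pooled_num / pooled_den if pooled_den else np.nan,
                "mean_proportion": sub["proportion"].mean(),
                "sd_proportion": sub["proportion"].std(ddof=1),
            }
        )
    return MethylationLevel(individual_levels=ind, population_levels=pd.DataFrame(pop_rows))


def state_proportions(states: StateMatrix) -> pd.DataFrame:
    """Per-population proportions of Types I-IV plus the pooled methylation level.

    The shape of the per-population state-frequency summaries used for
    stacked-bar reporting: columns Type I..IV sum to 1 per population;
    ``methylated`` is the pooled (II+III)/(I+II+III) level.
    """
    rows = []
    for pop in pd.unique(states.populations):
        sub = states.states[states.populations == pop]
        total = sub.size
        c = {t: int((sub == code).sum()) for t, code in (("I", 1), ("II", 2), ("III", 3), ("IV", 4))}
        scorable = c["I"] + c["II"] + c["III"]
        rows.append(
            {
                "population": pop,
                "type_i": c["I"] / total,
                "type_ii": c["II"] / total,
                "type_iii": c["III"] / total,
                "type_iv": c["IV"] / total,
                "methylated": (c["II"] + c["III"]) / scorable if scorable else np.nan,
            }
        )
    return pd.DataFrame(rows)
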