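"""Transcript populations and temperature scaling of their rates.

Each transcript is described by two warm-state (37 degC) rates: a
synthesis rate v_sr (mRNAs/min) and a first-order degradation rate k_dr
(per min), with warm steady state v_sr / k_dr.  Rates are sampled from
lognormal distributions -- synthesis directly, degradation via a
lognormal half-life in hours (k = ln 2 / half-life).

Temperature enters through Q10 scaling, rate(Tb) =
rate(37) * Q10**((Tb - 37)/10), with a larger Q10 for synthesis than
degradation so cooling shifts the balance toward degradation, and with
synthesis arrested entirely below a cutoff temperature (transcription
effectively ceases in deep torpor).

Three candidate mechanisms can protect a small transcript subset:

1. ``elevated_transcription`` -- the protected subset's synthesis-rate
   distribution is shifted to a higher log-mean (``mu_shift``), with the
   degradation rate raised to match the warm steady state
   (``matched_degradation``) or the steady state allowed to grow
   (``steady_state``).
2. ``reduced_degradation`` -- the protected subset's half-life log-mean
   is shifted up, with synthesis lowered to match steady state
   (``matched_transcription``) or steady state allowed to grow.
3. ``temp_protection`` -- rates are sampled exactly as for bulk, but at
   run time, whenever Tb drops below ``threshold_tb``, the protected
   subset's degradation is clamped to ``protection_fraction`` of its
   warm value (default: 3% below 10 degC).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "RateDistributionSpec",
    "PopulationSpec",
    "ThermalSensitivity",
    "ProtectionMechanism",
    "TranscriptParams",
    "Population",
    "sample_population",
    "scaled_rate",
    "effective_rates",
]

LN2 = math.log(2.0)

MECHANISM_VARIANTS = (
    "none",
    "elevated_transcription",
    "reduced_degradation",
    "temp_protection",
)
COMPENSATIONS = ("matched_degradation", "matched_transcription", "steady_state", "none")


@dataclass(frozen=True)
class RateDistributionSpec:
    """Lognormal parameters for warm-state rates.

    mu_syn / sigma_syn: natural-log mean and sd of the synthesis rate
    (mRNAs/min).  mu_halflife / sigma_halflife: natural-log mean and sd
    of the half-life (hours).
    """

    mu_syn: float = 0.033
    sigma_syn: float = 0.1
    mu_halflife: float = 2.5
    sigma_halflife: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma_syn < 0 or self.sigma_halflife < 0:
            raise ConfigurationError("lognormal sigmas must be >= 0")
        for mu in (self.mu_syn, self.mu_halflife):
            if not math.isfinite(math.exp(mu)):
                raise ConfigurationError("lognormal log-means must be finite")

    def mean_degradation_rate(self) -> float:
        """Closed-form population mean of k_dr (per min).

        k = (ln2/60) / h with h lognormal, so
        E[k] = (ln2/60) * exp(-mu + sigma^2 / 2).
        """
        return (LN2 / 60.0) * math.exp(-self.mu_halflife + self.sigma_halflife**2 / 2)

    def mean_synthesis_rate(self) -> float:
        """Closed-form population mean of v_sr (mRNAs/min)."""
        return math.exp(self.mu_syn + self.sigma_syn**2 / 2)


@dataclass(frozen=True)
class PopulationSpec:
    """Sizes and rate distributions for the simulated population.

    The default 1,400 bulk + 50 protected transcripts keeps the
    protected share close to the 531 / 14,267 ratio of stabilized to
    total tags seen in the sequencing data the model emulates.
    """

    n_bulk: int = 1400
    n_protected: int = 50
    bulk_rates: RateDistributionSpec = RateDistributionSpec()
    protected_rates: RateDistributionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bulk <= 0 or self.n_protected <= 0:
            raise ConfigurationError("population counts must be positive")

    @property
    def n_total(self) -> int:
        return self.n_bulk + self.n_protected


@dataclass(frozen=True)
class ThermalSensitivity:
    """Q10 coefficients and the transcription-arrest cutoff.

    q10_syn > q10_deg makes the steady-state ratio v/k fall as Tb falls,
    i.e. cooling favors degradation.  Below ``transcription_arrest_tb``
    synthesis is zero regardless of Q10 scaling.
    """

    q10_deg: float = 2.0
    q10_syn: float = 3.0
    t_ref: float = 37.0
    transcription_arrest_tb: float = 18.0

    def __post_init__(self) -> None:
        if self.q10_deg <= 1 or self.q10_syn <= 1:
            raise ConfigurationError("Q10 values must exceed 1")
        if not (0.0 <= self.transcription_arrest_tb < self.t_ref):
            raise ConfigurationError(
                "transcription arrest temperature must lie in [0, t_ref)"
            )


@dataclass(frozen=True)
class ProtectionMechanism:
    variant: str = "none"
    compensation: str = "none"
    threshold_tb: float = 10.0
    protection_fraction: float = 0.03
    mu_shift: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in MECHANISM_VARIANTS:
            raise ConfigurationError(
                f"variant {self.variant!r} not one of {MECHANISM_VARIANTS}"
            )
        if self.compensation not in COMPENSATIONS:
            raise ConfigurationError(
                f"compensation {self.compensation!r} not one of {COMPENSATIONS}"
            )
        if not (0.0 < self.protection_fraction <= 1.0):
            raise ConfigurationError("protection fraction must be in (0, 1]")
        if self.variant in ("elevated_transcription", "reduced_degradation"):
            if self.mu_shift is None:
                raise ConfigurationError(f"{self.variant} requires mu_shift")
            if self.compensation == "none":
                raise ConfigurationError(
                    f"{self.variant} requires an explicit compensation scheme"
                )
        elif self.compensation != "none":
            raise ConfigurationError(
                "compensation applies only to the fixed-alteration mechanisms"
            )

    # -- convenience constructors ------------------------------------
    @classmethod
    def none(cls) -> "ProtectionMechanism":
        return cls()

    @classmethod
    def temp_protection(
        cls, threshold_tb: float = 10.0, protection_fraction: float = 0.03
    ) -> "ProtectionMechanism":
        return cls(
            variant="temp_protection",
            threshold_tb=threshold_tb,
            protection_fraction=protection_fraction,
        )

    @classmethod
    def elevated_transcription(
        cls, mu_shift: float, compensation: str = "matched_degradation"
    ) -> "ProtectionMechanism":
        return cls(
            variant="elevated_transcription",
            compensation=compensation,
            mu_shift=mu_shift,
        )

    @classmethod
    def reduced_degradation(
        cls, mu_shift: float, compensation: str = "matched_transcription"
    ) -> "ProtectionMechanism":
        return cls(
            variant="reduced_degradation",
            compensation=compensation,
            mu_shift=mu_shift,
        )


@dataclass(frozen=True)
class TranscriptParams:
    """Warm-state parameters of a single transcript."""

    v_sr_warm: float
    k_dr_warm: float
    protected: bool

    def __post_init__(self) -> None:
        if self.v_sr_warm <= 0 or self.k_dr_warm <= 0:
            raise ConfigurationError("rates must be strictly positive")

    @property
    def half_life_hr(self) -> float:
        return LN2 / self.k_dr_warm / 60.0

    @property
    def steady_state_warm(self) -> float:
        return self.v_sr_warm / self.k_dr_warm


class Population:
    """Vectorized container for a sampled transcript population.

    Iterating or indexing yields :class:`TranscriptParams`; the arrays
    ``v_sr_warm``, ``k_dr_warm`` and the boolean ``protected`` mask are
    what the integrator consumes.
    """

    def __init__(
        self,
        v_sr_warm: np.ndarray,
        k_dr_warm: np.ndarray,
        protected: np.ndarray,
        spec: PopulationSpec | None = None,
        mechanism: ProtectionMechanism | None = None,
        ids: list[str] | None = None,
    ):
        self.v_sr_warm = np.asarray(v_sr_warm, dtype=float)
        self.k_dr_warm = np.asarray(k_dr_warm, dtype=float)
        self.protected = np.asarray(protected, dtype=bool)
        if not (len(self.v_sr_warm) == len(self.k_dr_warm) == len(self.protected)):
            raise ConfigurationError("population arrays must share one length")
        if np.any(self.v_sr_warm <= 0) or np.any(self.k_dr_warm <= 0):
            raise ConfigurationError("rates must be strictly positive")
        self.spec = spec
        self.mechanism = mechanism
        self.ids = ids or [f"tx_{i:05d}" for i in range(len(self.v_sr_warm))]

    def __len__(self) -> int:
        return len(self.v_sr_warm)

    def __getitem__(self, i: int) -> TranscriptParams:
        return TranscriptParams(
            float(self.v_sr_warm[i]), float(self.k_dr_warm[i]), bool(self.protected[i])
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def half_life_hr(self) -> np.ndarray:
        return LN2 / self.k_dr_warm / 60.0

    @property
    def steady_state_warm(self) -> np.ndarray:
        return self.v_sr_warm / self.k_dr_warm

    def to_tsv(self, path=None) -> str | None:
        buf = io.StringIO()
        buf.write(
            "transcript_id\tv_sr_warm\tk_dr_warm\thalf_life_hr\tsteady_state\tprotected\n"
        )
        hl, ss = self.half_life_hr, self.steady_state_warm
        for i, tid in enumerate(self.ids):
            buf.write(
                f"{tid}\t{self.v_sr_warm[i]:.8g}\t{self.k_dr_warm[i]:.8g}"
                f"\t{hl[i]:.8g}\t{ss[i]:.8g}\t{int(self.protected[i])}\n"
            )
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def sample_population(
    spec: PopulationSpec,
    mechanism: ProtectionMechanism = ProtectionMechanism(),
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw warm-state rates for bulk and protected transcripts.

    Bulk transcripts always come from ``spec.bulk_rates``.  The
    protected subset starts from ``spec.protected_rates`` (bulk by
    default); for the fixed-alteration mechanisms its relevant log-mean
    is then moved to ``mechanism.mu_shift`` by a quantile-preserving
    multiplicative shift, and the chosen compensation is applied.  For
    ``temp_protection`` (and ``none``) the protected draws are left
    untouched -- only run-time rates differ.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    prot_spec = spec.protected_rates or spec.bulk_rates

    def draw(n: int, d: RateDistributionSpec):
        v = rng.lognormal(d.mu_syn, d.sigma_syn, n)
        hl_hr = rng.lognormal(d.mu_halflife, d.sigma_halflife, n)
        k = LN2 / hl_hr / 60.0
        return v, k

    v_b, k_b = draw(spec.n_bulk, spec.bulk_rates)
    v_p, k_p = draw(spec.n_protected, prot_spec)

    if mechanism.variant == "elevated_transcription":
        shift = math.exp(mechanism.mu_shift - prot_spec.mu_syn)
        ss0 = v_p / k_p
        v_p = v_p * shift
        if mechanism.compensation == "matched_degradation":
            k_p = v_p / ss0
        elif mechanism.compensation == "matched_transcription":
            raise ConfigurationError(
                "matched_transcription does not apply to elevated transcription"
            )
        # steady_state: k unchanged, steady state grows
    elif mechanism.variant == "reduced_degradation":
        # mu_shift is a half-life log-mean; larger mu -> smaller k
        shift = math.exp(-(mechanism.mu_shift - prot_spec.mu_halflife))
        ss0 = v_p / k_p
        k_p = k_p * shift
        if mechanism.compensation == "matched_transcription":
            v_p = k_p * ss0
        elif mechanism.compensation == "matched_degradation":
            raise ConfigurationError(
                "matched_degradation does not apply to reduced degradation"
            )
        # steady_state: v unchanged, steady state grows

    protected = np.zeros(spec.n_total, dtype=bool)
    protected[spec.n_bulk :] = True
    return Population(
        np.concatenate([v_b, v_p]),
        np.concatenate([k_b, k_p]),
        protected,
        spec=spec,
        mechanism=mechanism,
    )


def scaled_rate(rate_warm, q10: float, tb, t_ref: float = 37.0):
    """Q10 temperature scaling: rate(Tb) = rate(T_ref) * Q10**((Tb-T_ref)/10)."""
    return rate_warm * q10 ** ((np.asarray(tb, dtype=float) - t_ref) / 10.0)


def effective_rates(
    population: Population | TranscriptParams,
    sens: ThermalSensitivity,
    mechanism: ProtectionMechanism,
    tb: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous synthesis and degradation rates at body temperature ``tb``.

    Synthesis is zero below the arrest temperature, Q10-scaled above it.
    Degradation is Q10-scaled, except that protected transcripts under
    ``temp_protection`` with Tb strictly below the threshold have
    k clamped to ``protection_fraction`` of the warm rate.  Unprotected
    transcripts are never touched by the mechanism.
    """
    if isinstance(population, TranscriptParams):
        pop = Population(
            [population.v_sr_warm], [population.k_dr_warm], [population.protected]
        )
        v, k = effective_rates(pop, sens, mechanism, tb)
        return float(v[0]), float(k[0])

    v_warm, k_warm = population.v_sr_warm, population.k_dr_warm
    if tb < sens.transcription_arrest_tb:
        v_eff = np.zeros_like(v_warm)
    else:
        v_eff = np.asarray(scaled_rate(v_warm, sens.q10_syn, tb, sens.t_ref))
    k_eff = np.asarray(scaled_rate(k_warm, sens.q10_deg, tb, sens.t_ref))
    if mechanism.variant == "temp_protection" and tb < mechanism.threshold_tb:
        mask = population.protected
        k_eff = np.where(mask, mechanism.protection_fraction * k_warm, k_eff)
    return v_eff, k_eff


def with_seed(spec: PopulationSpec, seed: int) -> PopulationSpec:
    """Copy of ``spec`` with a replaced RNG seed."""
    return replace(spec, seed=seed)
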