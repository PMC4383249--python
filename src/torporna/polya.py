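"""Poly(A)-fraction analysis: qPCR normalization, recovery statistics,
and Class I / IIA / IIB transcript classification.

Transcript abundance is measured by RT-qPCR in three RNA fractions --
total RNA, short-poly(A) (~25 nt tails) and long-poly(A) (>25 nt) --
across four physiological states (interbout arousal IBA, late torpor
LT, early arousal EAr, spring warm SpW; three animals each).

Loading differences between samples are corrected without a
housekeeping gene: each transcript's abundance in a sample is expressed
as a fold over the within-group median across samples, and the mean of
those folds over all transcripts is that sample's normalization factor.

Classes describe transcript behavior through a torpor bout:

* Class I   -- degraded: total RNA (and the poly(A) fractions) fall
               significantly from IBA to LT.
* Class IIA -- stable total RNA with significant gains in both poly(A)
               fractions at LT/EAr (poly(A)-tail acquisition).
* Class IIB -- total RNA falls but the polyadenylated fraction holds
               steady, so percent recovery rises.

"Significant" means one-way ANOVA across the four states at alpha
(default 0.05); directions compare LT (and EAr) means to IBA.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "DEFAULT_STATES",
    "QpcrTable",
    "FractionProfile",
    "ClassAssignment",
    "qpcr_normalization_factors",
    "apply_normalization",
    "percent_recovery",
    "long_short_ratio",
    "spearman_to_tag",
    "classify_transcript",
    "remove_outliers_mad",
    "anova_across_states",
]

DEFAULT_STATES = ("IBA", "LT", "EAr", "SpW")
FRACTIONS = ("total", "short", "long")


@dataclass
class QpcrTable:
    """Transcript x sample abundance table with group labels.

    ``values`` holds positive abundances (arbitrary concentration
    units; NaN marks an explicitly missing cell).  ``groups`` maps
    sample id -> state label; each group needs >= 2 samples.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ConfigurationError(f"samples without group label: {sorted(missing)}")
        sizes = self.groups.loc[self.values.columns].value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise ConfigurationError(
                f"groups with fewer than two samples: {dict(small)}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ConfigurationError("abundances must be non-negative")

    def group_columns(self) -> dict[str, list[str]]:
        g = self.groups.loc[self.values.columns]
        return {label: list(cols) for label, cols in g.groupby(g).groups.items()}


def qpcr_normalization_factors(table: QpcrTable) -> pd.Series:
    """Per-sample loading-correction factors.

    factor(s) = mean over transcripts of
    value(transcript, s) / median over the samples of s's group of
    value(transcript, .).  Transcripts whose within-group median is
    zero (or missing) are excluded from that sample's mean with a
    warning.
    """
    factors = {}
    n_excluded = 0
    for _, cols in table.group_columns().items():
        block = table.values[cols]
        med = block.median(axis=1)
        ok = med > 0
        n_excluded += int((~ok & med.notna()).sum())
        for s in cols:
            folds = block.loc[ok, s] / med[ok]
            factors[s] = float(folds.mean())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} transcript(s) with zero within-group median excluded "
            "from factor estimation",
            stacklevel=2,
        )
    return pd.Series(factors).loc[table.values.columns].rename("factor")


def apply_normalization(table: QpcrTable, factors: pd.Series | None = None) -> QpcrTable:
    """Divide each sample's values by its normalization factor."""
    if factors is None:
        factors = qpcr_normalization_factors(table)
    return QpcrTable(table.values.div(factors, axis=1), table.groups)


def percent_recovery(fraction_value, total_value):
    """Poly(A)-fraction abundance as a percentage of total RNA.

    Zero total leaves the ratio undefined; reported as NaN.
    """
    fraction_value = np.asarray(fraction_value, dtype=float)
    total_value = np.asarray(total_value, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total_value > 0, 100.0 * fraction_value / total_value, np.nan)
    return out if out.ndim else float(out)


def long_short_ratio(long_values, short_values):
    """Mean-scaled long:short poly(A) ratio per state.

    An increase marks poly(A)-tail lengthening, a decrease shortening.
    States with a zero short-fraction value are flagged missing (NaN)
    and excluded from the scaling mean.
    """
    long_values = np.asarray(long_values, dtype=float)
    short_values = np.asarray(short_values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(short_values > 0, long_values / short_values, np.nan)
    m = np.nanmean(ratio)
    return ratio / m


def spearman_to_tag(profile_means, tag_means) -> tuple[float, float]:
    """Spearman rank correlation between a fraction profile and its tag.

    Ties get mid-ranks.  For <= 8 states the two-sided p-value is exact
    (full permutation distribution); beyond that the large-sample
    approximation is used.  Constant vectors have no defined rank
    correlation and return (nan, nan).
    """
    x = np.asarray(profile_means, dtype=float)
    y = np.asarray(tag_means, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired state values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = np.array(
            [np.corrcoef(rx[p], ry)[0, 1] for p in perms]
        )
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def anova_across_states(values_by_state: dict[str, np.ndarray]) -> float:
    """One-way ANOVA p-value across states, guarded for zero variance.

    With no within-group variance the F statistic is undefined; the
    p-value is then 0 if the group means differ and 1 if they do not
    (the noise-free limits of the test).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_state.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every state needs >= 2 replicate values")
    means = np.array([g.mean() for g in groups])
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    scale = max(abs(means).max(), 1e-300)
    if within / scale**2 < 1e-24:
        return 0.0 if np.ptp(means) / scale > 1e-12 else 1.0
    return float(stats.f_oneway(*groups).pvalue)


def remove_outliers_mad(values, n_mads: float = 3.0) -> np.ndarray:
    """Screen technical replicates by median absolute deviation.

    Values farther than ``n_mads`` scaled MADs from the median are
    dropped; with a zero MAD (two identical of three, say) only exact
    agreement survives, so everything is kept to avoid degenerate
    removal.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        return x
    return x[np.abs(x - med) <= n_mads * mad]


@dataclass
class FractionProfile:
    """Replicate-level abundances for one transcript.

    ``replicates``: fraction name -> {state -> replicate array}.
    ``tag_means``: optional per-state tag-count group means for the
    Spearman cross-check against the sequencing pattern.
    """

    transcript_id: str
    replicates: dict[str, dict[str, np.ndarray]]
    states: tuple[str, ...] = DEFAULT_STATES
    tag_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        for frac in FRACTIONS:
            if frac not in self.replicates:
                raise ConfigurationError(f"missing fraction {frac!r}")
            for s in self.states:
                if s not in self.replicates[frac]:
                    raise ConfigurationError(f"fraction {frac!r} missing state {s!r}")
                arr = np.asarray(self.replicates[frac][s], dtype=float)
                if (arr < 0).any():
                    raise ConfigurationError("abundances must be non-negative")

    def means(self, fraction: str) -> np.ndarray:
        return np.array(
            [np.mean(self.replicates[fraction][s]) for s in self.states]
        )

    def sems(self, fraction: str) -> np.ndarray:
        return np.array(
            [stats.sem(self.replicates[fraction][s]) for s in self.states]
        )

    def state_index(self, state: str) -> int:
        return self.states.index(state)


@dataclass
class ClassAssignment:
    transcript_id: str
    label: str  # "I", "IIA", "IIB" or "unclassified"
    stats: dict = field(default_factory=dict)


def classify_transcript(
    profile: FractionProfile, alpha: float = 0.05, polya_rule: str = "both"
) -> ClassAssignment:
    """Assign a transcript to Class I, IIA, IIB or unclassified.

    The decision list, applied in order:

    1. Class I if total RNA changes significantly with LT below IBA and
       the poly(A) fractions significantly fall with it.
    2. Class IIA if the poly(A) fractions rise significantly at LT/EAr
       (total RNA stability is what rule 1 has not already claimed).
    3. Class IIB if total RNA falls significantly while the poly(A)
       fractions show no significant change.

    ``polya_rule`` pools the short- and long-fraction ANOVAs: "both"
    (default) calls a poly(A) change only when each fraction is
    individually significant -- the stabilized class gains material in
    both fractions -- while "any" accepts either.  All test statistics
    are recorded for audit regardless of the label.
    """
    if polya_rule not in ("both", "any"):
        raise ConfigurationError("polya_rule must be 'both' or 'any'")

    i_iba = profile.state_index("IBA")
    i_lt = profile.state_index("LT")
    i_ear = profile.state_index("EAr")

    p = {}
    direction_up = {}
    for frac in FRACTIONS:
        by_state = {s: profile.replicates[frac][s] for s in profile.states}
        p[frac] = anova_across_states(by_state)
        m = profile.means(frac)
        if frac == "total":
            direction_up[frac] = m[i_lt] > m[i_iba]
        else:
            direction_up[frac] = (m[i_lt] + m[i_ear]) / 2.0 > m[i_iba]

    total_sig = p["total"] < alpha
    total_down = not direction_up["total"]
    sig = {f: p[f] < alpha for f in ("short", "long")}
    if polya_rule == "both":
        polya_sig = sig["short"] and sig["long"]
    else:
        polya_sig = sig["short"] or sig["long"]
    polya_up = polya_sig and direction_up["short"] and direction_up["long"]
    polya_down = polya_sig and not direction_up["short"] and not direction_up["long"]

    audit = {
        "p_total": p["total"],
        "p_short": p["short"],
        "p_long": p["long"],
        "total_down_lt_vs_iba": total_down,
        "polya_sig": polya_sig,
        "polya_up": polya_up,
        "polya_down": polya_down,
    }
    if profile.tag_means is not None:
        for frac in FRACTIONS:
            rho, pv = spearman_to_tag(profile.means(frac), profile.tag_means)
            audit[f"rho_{frac}_vs_tag"] = rho
            audit[f"p_rho_{frac}_vs_tag"] = pv

    if total_sig and total_down and polya_down:
        label = "I"
    elif polya_up:
        label = "IIA"
    elif total_sig and total_down and not polya_sig:
        label = "IIB"
    else:
        label = "unclassified"
    return ClassAssignment(profile.transcript_id, label, audit)
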