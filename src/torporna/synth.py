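"""Synthetic fixtures with planted ground truth.

Three generators emulate the study's data shapes:

* grouped tag-count matrices -- eight physiological groups of 4-6
  animals, negative-binomial counts around six planted mean-scaled
  expression archetypes, a tag-level platform bias carried by the
  later-sequenced groups, and cross-platform technical-replicate pairs;
* poly(A) fraction profiles for the three transcript classes
  (I / IIA / IIB) with multiplicative lognormal replicate noise;
* qPCR tables with planted per-sample loading factors.

Every generator is driven by one seed and emits a
:class:`PlantedTruth` sufficient to score recovery; scoring utilities
here use only that truth, never external data.

The six archetypes are stylized single-peak patterns over the group
axis -- two spring/summer-high and four winter-high with peaks at
interbout arousal/entrance, early torpor, late torpor and early
arousal.  Real cluster centroids overlap more; only the pattern
topology matters for exercising the clustering pipeline, and the
stylization keeps the planted partition identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .polya import DEFAULT_STATES, FractionProfile, QpcrTable
from .tags import DEFAULT_GROUP_ORDER, TagCountMatrix

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_ARCHETYPES",
    "FRACTION_TEMPLATES",
    "TagSimConfig",
    "PlantedTruth",
    "generate_tag_counts",
    "generate_fraction_profiles",
    "generate_qpcr_true_table",
    "generate_qpcr_with_loading",
    "adjusted_rand_index",
    "score_cluster_recovery",
]

#: eight physiological groups with the study's sample sizes
DEFAULT_GROUP_SIZES = {
    "SpW": 6, "SpC": 5, "SA": 5, "IBA": 4, "Ent": 5, "ET": 4, "LT": 4, "EAr": 5,
}

#: six mean-scaled expression archetypes over the group axis
#: (SpW, SpC, SA, IBA, Ent, ET, LT, EAr)
_ARCH_RAW = {
    1: (2.6, 2.4, 0.8, 0.4, 0.3, 0.3, 0.3, 0.3),   # spring-high
    2: (0.7, 0.5, 3.4, 0.5, 0.4, 0.3, 0.3, 0.3),   # summer-active high
    3: (0.3, 0.3, 0.3, 2.8, 2.0, 0.5, 0.4, 0.4),   # interbout/entrance high
    4: (0.3, 0.3, 0.3, 0.5, 0.9, 3.2, 0.8, 0.5),   # early-torpor peak
    5: (0.3, 0.3, 0.3, 0.4, 0.4, 0.8, 3.2, 1.2),   # late-torpor peak
    6: (0.3, 0.3, 0.3, 0.5, 0.3, 0.4, 1.0, 3.4),   # early-arousal peak
}
DEFAULT_ARCHETYPES = pd.DataFrame(
    {k: np.asarray(v) / np.mean(v) for k, v in _ARCH_RAW.items()},
    index=list(DEFAULT_GROUP_ORDER),
).T

#: poly(A) fraction templates per class over (IBA, LT, EAr, SpW).
#: I: total and poly(A) fall in torpor and rebound by spring, long tails
#: shortening; IIA: flat total, both poly(A) fractions rise at LT/EAr with
#: the long fraction rising more (tail lengthening); IIB: total falls at
#: LT/EAr while the poly(A) fractions hold (percent recovery rises).
FRACTION_TEMPLATES = {
    "I": {
        "total": (1.0, 0.35, 0.55, 1.1),
        "short": (1.0, 0.55, 0.60, 1.0),
        "long": (1.0, 0.30, 0.45, 1.15),
        "tag": (1.0, 0.40, 0.55, 1.1),
    },
    "IIA": {
        "total": (1.0, 1.0, 1.0, 1.0),
        "short": (1.0, 2.0, 2.6, 1.0),
        "long": (1.0, 2.6, 3.6, 1.0),
        "tag": (1.0, 2.2, 3.0, 1.0),
    },
    "IIB": {
        "total": (1.0, 0.45, 0.50, 1.0),
        "short": (1.0, 1.0, 1.0, 1.0),
        "long": (1.0, 1.0, 1.0, 1.0),
        "tag": (1.0, 1.7, 1.9, 1.0),
    },
}


@dataclass(frozen=True)
class TagSimConfig:
    """Parameters of the tag-count simulator."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_tags: int = 400
    n_de: int = 240
    n_null: int = 20
    archetypes: pd.DataFrame | None = None
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (1e6, 1e7)
    platform_groups: tuple[str, ...] = ("ET", "SA")
    platform_bias: float = 4.0
    biased_tag_fraction: float = 0.1
    n_replicate_pairs: int = 2
    base_log_tpm_mean: float = float(np.log(50.0))
    base_log_tpm_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de + self.n_null > self.n_tags:
            raise ConfigurationError("n_de + n_null cannot exceed n_tags")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        arch = self.archetypes if self.archetypes is not None else DEFAULT_ARCHETYPES
        if len(arch) < 1:
            raise ConfigurationError("need at least one archetype")
        missing = set(arch.columns) - set(self.group_sizes)
        if missing:
            raise ConfigurationError(f"archetype groups without sizes: {missing}")

    @property
    def arch(self) -> pd.DataFrame:
        return self.archetypes if self.archetypes is not None else DEFAULT_ARCHETYPES


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every fixture."""

    archetype: pd.Series | None = None          # tag -> archetype label (NA = flat)
    expected_tpm: pd.DataFrame | None = None    # tag x group expected TPM (pre-bias)
    library_size: pd.Series | None = None       # sample -> expected library size
    platform: pd.Series | None = None           # sample -> platform label
    biased_tags: pd.Index | None = None         # tags carrying the platform bias
    loading_factors: pd.Series | None = None    # sample -> loading multiplier
    class_label: dict | None = None             # transcript -> class
    seed: int | None = None


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draws with var = m + dispersion * m**2 via
    gamma-Poisson mixing; the zero-dispersion limit returns rounded means."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def generate_tag_counts(config: TagSimConfig) -> tuple[TagCountMatrix, PlantedTruth]:
    """Simulate a grouped tag-count matrix with planted structure.

    The first ``n_de`` tags carry the archetype patterns in equal
    blocks; the last ``n_null`` are unexpressed (zero mean everywhere,
    exercising the expression floor); the rest are flat.  Samples of
    the designated platform
    groups, plus the technical-replicate columns, are sequenced on
    platform B, where a planted subset of tags is multiplied by
    ``platform_bias``.  Replicate columns are independent count draws
    around the same biological mean as their partner (modulo the
    per-platform bias), emulating a resequenced library.
    """
    rng = np.random.default_rng(config.seed)
    arch = config.arch
    groups_order = [g for g in DEFAULT_GROUP_ORDER if g in config.group_sizes]
    groups_order += [g for g in config.group_sizes if g not in groups_order]

    samples, sample_group = [], {}
    for g in groups_order:
        for i in range(config.group_sizes[g]):
            sid = f"{g}_{i + 1}"
            samples.append(sid)
            sample_group[sid] = g
    platform = {
        s: ("B" if sample_group[s] in config.platform_groups else "A")
        for s in samples
    }

    # technical replicates: first platform-A samples, resequenced on B
    a_samples = [s for s in samples if platform[s] == "A"]
    partners: dict[str, str] = {}
    for s in a_samples[: config.n_replicate_pairs]:
        rep = f"{s}_rep"
        samples.append(rep)
        sample_group[rep] = sample_group[s]
        platform[rep] = "B"
        partners[s] = rep
        partners[rep] = s

    tag_ids = [f"tag_{i:04d}" for i in range(config.n_tags)]
    labels = pd.Series(pd.NA, index=tag_ids, dtype="object", name="archetype")
    arch_labels = list(arch.index)
    block = config.n_de // len(arch_labels)
    for ai, a in enumerate(arch_labels):
        start = ai * block
        stop = config.n_de if ai == len(arch_labels) - 1 else (ai + 1) * block
        labels.iloc[start:stop] = a

    base_tpm = rng.lognormal(
        config.base_log_tpm_mean, config.base_log_tpm_sd, config.n_tags
    )
    if config.n_null:
        base_tpm[config.n_tags - config.n_null :] = 0.0
    n_biased = int(round(config.biased_tag_fraction * config.n_tags))
    biased = pd.Index(rng.choice(tag_ids, size=n_biased, replace=False)).sort_values()
    biased_mask = np.isin(tag_ids, biased)

    lib = pd.Series(
        rng.uniform(*config.libsize_range, size=len(samples)), index=samples
    )

    pattern = np.ones((config.n_tags, len(groups_order)))
    gindex = {g: j for j, g in enumerate(groups_order)}
    for ai, a in enumerate(arch_labels):
        rows = (labels == a).to_numpy()
        pattern[rows] = arch.loc[a, groups_order].to_numpy()

    counts = np.empty((config.n_tags, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        tpm = base_tpm * pattern[:, gindex[sample_group[s]]]
        if platform[s] == "B":
            tpm = np.where(biased_mask, tpm * config.platform_bias, tpm)
        mean = tpm / 1e6 * lib[s]
        counts[:, j] = _nb_counts(rng, mean, config.dispersion)

    meta = pd.DataFrame(
        {
            "group": [sample_group[s] for s in samples],
            "platform": [platform[s] for s in samples],
            "replicate_partner": [partners.get(s) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    matrix = TagCountMatrix(
        pd.DataFrame(counts, index=pd.Index(tag_ids, name="tag_id"), columns=samples),
        meta,
    )
    truth = PlantedTruth(
        archetype=labels,
        expected_tpm=pd.DataFrame(
            base_tpm[:, None] * pattern, index=tag_ids, columns=groups_order
        ),
        library_size=lib,
        platform=pd.Series(platform).loc[samples],
        biased_tags=biased,
        seed=config.seed,
    )
    return matrix, truth


def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise at the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(-(sigma**2) / 2.0, sigma, size)


def generate_fraction_profiles(
    class_label: str,
    noise_cv: float = 0.1,
    seed: int = 0,
    n_reps: int = 3,
    transcript_id: str | None = None,
) -> FractionProfile:
    """One transcript's replicate-level fraction profile for a class."""
    if class_label not in FRACTION_TEMPLATES:
        raise ValueError(f"unknown class label {class_label!r}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    template = FRACTION_TEMPLATES[class_label]
    reps = {
        frac: {
            s: template[frac][i] * _lognormal_noise(rng, noise_cv, n_reps)
            for i, s in enumerate(DEFAULT_STATES)
        }
        for frac in ("total", "short", "long")
    }
    return FractionProfile(
        transcript_id=transcript_id or f"class{class_label}_synthetic",
        replicates=reps,
        states=DEFAULT_STATES,
        tag_means=np.asarray(template["tag"], dtype=float),
    )


def generate_qpcr_true_table(
    n_transcripts: int = 12,
    groups: dict[str, int] | None = None,
    seed: int = 0,
) -> QpcrTable:
    """Bias-free qPCR abundances: per-transcript levels with mild
    transcript-by-group effects and no sample-level artifacts."""
    if groups is None:
        groups = {s: 3 for s in DEFAULT_STATES}
    rng = np.random.default_rng(seed)
    samples, labels = [], {}
    for g, n in groups.items():
        for i in range(n):
            sid = f"{g}_{i + 1}"
            samples.append(sid)
            labels[sid] = g
    level = rng.lognormal(0.0, 1.0, n_transcripts)
    effect = rng.lognormal(0.0, 0.3, (n_transcripts, len(groups)))
    cols = {}
    for j, s in enumerate(samples):
        gi = list(groups).index(labels[s])
        cols[s] = level * effect[:, gi]
    values = pd.DataFrame(
        cols, index=[f"tx_{i + 1:02d}" for i in range(n_transcripts)]
    )
    return QpcrTable(values, pd.Series(labels))


def generate_qpcr_with_loading(
    true_table: QpcrTable,
    loading_factors: pd.Series,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[QpcrTable, PlantedTruth]:
    """Corrupt a true table with per-sample loading factors and noise.

    observed(t, s) = true(t, s) * loading(s) * lognormal noise.
    """
    loading = pd.Series(loading_factors).loc[true_table.values.columns]
    if (loading <= 0).any():
        raise ConfigurationError("loading factors must be positive")
    rng = np.random.default_rng(seed)
    noise = _lognormal_noise(rng, noise_cv, true_table.values.shape)
    observed = true_table.values * loading * noise
    truth = PlantedTruth(loading_factors=loading, seed=seed)
    return QpcrTable(observed, true_table.groups), truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index by pair counting (chance-corrected agreement)."""
    a = pd.factorize(np.asarray(labels_a))[0]
    b = pd.factorize(np.asarray(labels_b))[0]
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    n = len(a)
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    for i, j in zip(a, b):
        table[i, j] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_idx = (sum_a + sum_b) / 2.0
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))


def score_cluster_recovery(truth_labels: pd.Series, assignment: pd.Series) -> dict:
    """Compare a cluster assignment against planted archetype labels.

    Only tags with a planted label are scored (flat background tags
    have no true cluster).
    """
    common = truth_labels.dropna().index.intersection(assignment.index)
    t = truth_labels.loc[common]
    a = assignment.loc[common]
    return {
        "n_scored": int(len(common)),
        "n_clusters": int(a.nunique()),
        "ari": adjusted_rand_index(t.to_numpy(), a.to_numpy()),
    }
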