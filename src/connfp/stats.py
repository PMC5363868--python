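"""Permutation-based group comparison and feature selection.

For each region and each pairwise group comparison the observed statistic is
the absolute difference of group means (a Welch t statistic is available via
config).  The null distribution is built by randomly reassigning all subjects
to the three groups (original sizes preserved) and recomputing every pairwise
statistic.  Family-wise correction uses the Westfall–Young maxT device: each
permutation contributes its maximum statistic across the regions of the
modality, within each comparison.  p-values include the observed statistic,
p = (1 + #{null >= observed}) / (1 + B), so p is never 0 and never below
1/(B+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_COMPARISONS = (("NC", "MCI"), ("NC", "AD"), ("MCI", "AD"))


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 5000
    alpha: float = 0.05
    correction: str = "maxT"  # or "none"
    seed: int = 0
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS
    statistic: str = "mean_diff"  # or "welch_t"

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("maxT", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.statistic not in ("mean_diff", "welch_t"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class PermutationTable:
    """Observed statistics and corrected p-values, one row set per modality."""

    modality: str
    region_names: list[str]
    comparisons: list[tuple[str, str]]
    observed: np.ndarray      # comparisons x regions
    p_values: np.ndarray      # comparisons x regions
    group_means: dict[str, np.ndarray]
    group_sds: dict[str, np.ndarray]
    n_permutations: int
    correction: str

    def to_dataframe(self) -> pd.DataFrame:
        """Region rows; per-group 'mean (SD)' columns; per-comparison p columns."""
        cols: dict[str, list] = {}
        for g, m in self.group_means.items():
            sd = self.group_sds[g]
            cols[g] = [f"{mi:.3f} ({si:.3f})" for mi, si in zip(m, sd)]
        for c, (a, b) in enumerate(self.comparisons):
            cols[f"p {a} vs {b}"] = np.round(self.p_values[c], 4)
        return pd.DataFrame(cols, index=self.region_names).rename_axis("region")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "region_names": self.region_names,
            "comparisons": [list(c) for c in self.comparisons],
            "observed": self.observed.tolist(),
            "p_values": self.p_values.tolist(),
            "group_means": {g: v.tolist() for g, v in self.group_means.items()},
            "group_sds": {g: v.tolist() for g, v in self.group_sds.items()},
            "n_permutations": self.n_permutations,
            "correction": self.correction,
        }


def _pairwise_stats(features: np.ndarray, labels: np.ndarray,
                    comparisons: Sequence[tuple[str, str]],
                    statistic: str) -> np.ndarray:
    """comparisons x regions statistic matrix for one labelling."""
    stats = np.empty((len(comparisons), features.shape[1]))
    cache: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for g in {g for pair in comparisons for g in pair}:
        x = features[labels == g]
        cache[g] = (x.mean(axis=0), x.var(axis=0, ddof=1), x.shape[0])
    for c, (a, b) in enumerate(comparisons):
        ma, va, na = cache[a]
        mb, vb, nb = cache[b]
        if statistic == "mean_diff":
            stats[c] = np.abs(ma - mb)
        else:  # welch_t
            denom = np.sqrt(va / na + vb / nb)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.abs(ma - mb) / denom
            stats[c] = np.where(denom == 0, 0.0, t)
    return stats


def permutation_test(features: np.ndarray, labels: Sequence[str],
                     cfg: PermutationConfig = PermutationConfig(),
                     region_names: Sequence[str] | None = None,
                     modality: str = "") -> PermutationTable:
    """Permutation test of group differences per region.

    ``features`` is subjects x regions; ``labels`` assigns each subject to a
    group. Every permutation reassigns all subjects to groups of the original
    sizes and recomputes each pairwise statistic, matching a whole-cohort
    relabelling scheme even for pairwise comparisons.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != len(labels):
        raise ValueError("features must be subjects x regions, aligned with labels")
    groups = sorted({g for pair in cfg.comparisons for g in pair})
    for g in groups:
        n_g = int((labels == g).sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} subject(s); need at least 2")
    if region_names is None:
        region_names = [f"region_{j}" for j in range(features.shape[1])]

    observed = _pairwise_stats(features, labels, cfg.comparisons, cfg.statistic)
    rng = np.random.default_rng(cfg.seed)
    b = cfg.n_permutations
    null = np.empty((b, *observed.shape))
    for i in range(b):
        null[i] = _pairwise_stats(features, rng.permutation(labels),
                                  cfg.comparisons, cfg.statistic)

    if cfg.correction == "maxT":
        # each permutation contributes its max across regions, per comparison
        ref = null.max(axis=2)[:, :, None]                  # b x C x 1
    else:
        ref = null                                          # b x C x R
    exceed = (ref >= observed[None]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + b)

    all_groups = sorted(set(labels))
    means = {g: features[labels == g].mean(axis=0) for g in all_groups}
    sds = {g: features[labels == g].std(axis=0, ddof=1) for g in all_groups}
    return PermutationTable(modality, list(region_names),
                            [tuple(c) for c in cfg.comparisons],
                            observed, p, means, sds, b, cfg.correction)


@dataclass
class FeatureSelection:
    selected: list[tuple[str, str]]  # (modality, region)
    alpha: float
    min_comparisons: int

    def __bool__(self) -> bool:
        return bool(self.selected)


def select_features(tables: Mapping[str, PermutationTable],
                    alpha: float = 0.05,
                    min_comparisons: int = 2) -> FeatureSelection:
    """Regions significant (p < alpha) in at least ``min_comparisons`` of the
    pairwise comparisons, pooled across modalities into one feature list."""
    selected: list[tuple[str, str]] = []
    for modality, table in tables.items():
        n_sig = (table.p_values < alpha).sum(axis=0)
        for j, region in enumerate(table.region_names):
            if n_sig[j] >= min_comparisons:
                selected.append((modality, region))
    if not selected:
        warnings.warn("no feature satisfied the selection rule; "
                      "classification will be refused on an empty feature set")
    return FeatureSelection(selected, alpha, min_comparisons)
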