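"""Connectional-fingerprint summaries.

A fingerprint is the per-group profile of a regional feature (eigenvector
centrality or volume) over the target regions: per-region mean with a 95%
t-interval, plus the area enclosed by the radar polygon whose i-th vertex
sits at polar radius mean_i and angle 2*pi*i/k.  The enclosed area is the
scalar summary of global degeneration: if one group dominates another at
every region (strictly somewhere), its area is strictly larger.

The area is invariant under cyclic rotation of the region order but not
under arbitrary permutation; profiles are therefore computed in one fixed
canonical region order so areas are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class FingerprintProfile:
    group: str
    region_order: list[str]
    region_means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    area: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {"group": self.group,
                "region_order": self.region_order,
                "region_means": self.region_means.tolist(),
                "ci_low": self.ci_low.tolist(),
                "ci_high": self.ci_high.tolist(),
                "area": self.area,
                "n_subjects": self.n_subjects}


def radar_area(region_means: Sequence[float]) -> float:
    """Shoelace area of the radar polygon: (1/2) sin(2*pi/k) * sum_i m_i m_{i+1}."""
    m = np.asarray(region_means, dtype=float)
    k = m.size
    if k < 3:
        raise ValueError("radar area needs at least 3 regions")
    if (m < 0).any():
        raise ValueError("radar area is defined for non-negative means")
    return float(0.5 * np.sin(2.0 * np.pi / k) * np.sum(m * np.roll(m, -1)))


def fingerprint_summary(features: np.ndarray, labels: Sequence[str],
                        region_names: Sequence[str],
                        confidence: float = 0.95) -> dict[str, FingerprintProfile]:
    """Per-group region means, t-intervals on the mean, and radar area."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape != (len(labels), len(region_names)):
        raise ValueError("features must be subjects x regions, aligned with "
                         "labels and region_names")
    profiles: dict[str, FingerprintProfile] = {}
    for g in sorted(set(labels)):
        x = features[labels == g]
        n = x.shape[0]
        if n < 2:
            raise ValueError(f"group {g!r} has a single subject; "
                             "confidence interval undefined")
        mean = x.mean(axis=0)
        half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * x.std(axis=0, ddof=1) / np.sqrt(n)
        profiles[g] = FingerprintProfile(
            group=str(g), region_order=list(region_names),
            region_means=mean, ci_low=mean - half, ci_high=mean + half,
            area=radar_area(np.clip(mean, 0.0, None)), n_subjects=n)
    return profiles


def plot_radar(profiles: Mapping[str, FingerprintProfile], path: str,
               colors: Mapping[str, str] | None = None) -> None:
    """Optional polar rendering of a set of fingerprints (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = next(iter(profiles.values()))
    k = len(first.region_order)
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    theta_closed = np.append(theta, theta[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for g, prof in profiles.items():
        r = np.append(prof.region_means, prof.region_means[0])
        kwargs = {"color": colors[g]} if colors and g in colors else {}
        ax.plot(theta_closed, r, label=f"{g} (area {prof.area:.4g})", **kwargs)
    ax.set_xticks(theta)
    ax.set_xticklabels(first.region_order, fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
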