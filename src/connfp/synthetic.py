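"""Synthetic three-group cohort generator.

Emulates the statistical structure of a resting-state fMRI study contrasting
normal controls (NC), mild cognitive impairment (MCI) and Alzheimer's disease
(AD): per-subject multivariate ROI time series with group-specific covariance
(optionally carrying planted "hub" connectivity effects in designated
subcortical ROIs) and per-region subcortical volumes drawn from group-specific
normal distributions.

The time-series model is a temporally white zero-mean multivariate normal;
Pearson correlation between ROI columns is the only downstream consumer, so
temporal autocorrelation structure is deliberately omitted (a band-pass can be
applied post hoc if band-limited series are wanted). Volumes are independent
across regions, truncated below at a small positive floor.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("NC", "MCI", "AD")

#: Canonical analysis order of the 10 subcortical target regions.
TARGET_ROI_NAMES = (
    "Thalamus_L", "Thalamus_R",
    "Putamen_L", "Putamen_R",
    "Hippocampus_L", "Hippocampus_R",
    "Caudate_L", "Caudate_R",
    "Amygdala_L", "Amygdala_R",
)

#: Default per-group (mean_cc, sd_cc) of the 10 target regions, in
#: TARGET_ROI_NAMES order.  Values are typical published group statistics for
#: elderly NC/MCI/AD cohorts and define the generator's study conditions.
DEFAULT_VOLUME_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "NC": ((9.54, 0.81), (9.31, 0.77), (5.83, 0.66), (5.95, 0.70),
           (4.66, 0.68), (4.96, 0.64), (4.27, 0.60), (4.63, 0.67),
           (1.73, 0.46), (1.58, 0.36)),
    "MCI": ((9.43, 0.81), (9.14, 0.76), (5.45, 1.06), (5.66, 0.98),
            (4.41, 0.77), (4.67, 0.80), (4.24, 0.54), (4.59, 0.50),
            (1.58, 0.32), (1.61, 0.30)),
    "AD": ((9.09, 1.04), (8.93, 0.96), (5.16, 0.92), (5.49, 0.97),
           (3.66, 0.76), (4.06, 0.83), (4.08, 0.60), (4.49, 0.67),
           (1.47, 0.28), (1.47, 0.29)),
}


def null_volume_params(group_params: Mapping[str, Sequence[tuple[float, float]]]
                       | None = None) -> dict[str, tuple[tuple[float, float], ...]]:
    """Identical volume distributions for all groups (the NC row everywhere).

    Combined with an empty effect list this yields a fully exchangeable null
    cohort, the substrate for type-I-error calibration.
    """
    src = group_params or DEFAULT_VOLUME_PARAMS
    nc = tuple(tuple(p) for p in src["NC"])
    return {g: nc for g in GROUPS}


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference.

    kind:
        ``hub_weaken`` / ``hub_strengthen`` — scale the off-diagonal row and
        column of ``roi_index`` in the group covariance by ``magnitude``
        (< 1 weakens, > 1 strengthens the region's connectivity).
        ``volume_shift`` — add ``magnitude`` cc to the group mean volume of
        the target region (``roi_index`` must be a target subcortical ROI).
    """

    target_group: str
    roi_index: int
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.target_group not in GROUPS:
            raise ValueError(f"unknown group {self.target_group!r}")
        if self.kind not in ("hub_weaken", "hub_strengthen", "volume_shift"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind in ("hub_weaken", "hub_strengthen") and self.magnitude <= 0:
            raise ValueError("hub scaling factor must be > 0")


def default_roi_names(n_rois: int) -> list[str]:
    """Generic cortical names with the 10 target regions in the last slots."""
    if n_rois < len(TARGET_ROI_NAMES):
        raise ValueError(f"n_rois must be >= {len(TARGET_ROI_NAMES)}")
    n_other = n_rois - len(TARGET_ROI_NAMES)
    return [f"Cortical_{i + 1:02d}" for i in range(n_other)] + list(TARGET_ROI_NAMES)


def default_target_indices(n_rois: int) -> list[int]:
    return list(range(n_rois - len(TARGET_ROI_NAMES), n_rois))


def default_group_effects(n_rois: int = 90) -> list[EffectSpec]:
    """Hub-weakening effects encoding the qualitative disease pattern.

    Left-hemisphere hippocampus connectivity weakens in MCI and further in AD;
    left putamen, thalamus and caudate weaken in AD.
    """
    idx = dict(zip(TARGET_ROI_NAMES, default_target_indices(n_rois)))
    return [
        EffectSpec("MCI", idx["Hippocampus_L"], "hub_weaken", 0.70),
        EffectSpec("AD", idx["Hippocampus_L"], "hub_weaken", 0.55),
        EffectSpec("AD", idx["Putamen_L"], "hub_weaken", 0.60),
        EffectSpec("AD", idx["Thalamus_L"], "hub_weaken", 0.70),
        EffectSpec("AD", idx["Caudate_L"], "hub_weaken", 0.70),
    ]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a typical three-group resting-state study: 35/40/30
    subjects, 90-ROI parcellation, 140 volumes at TR = 3 s, group-specific
    subcortical volume distributions, and hub-weakening connectivity effects
    in disease groups (``group_effects=None`` selects
    :func:`default_group_effects`; pass ``[]`` for a null cohort).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 35, "MCI": 40, "AD": 30})
    n_rois: int = 90
    n_timepoints: int = 140
    tr_seconds: float = 3.0
    group_effects: Sequence[EffectSpec] | None = None
    volume_params: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: {g: v for g, v in DEFAULT_VOLUME_PARAMS.items()})
    seed: int = 0
    # base covariance: two-level block-correlation structure
    n_blocks: int = 6
    base_within: float = 0.45
    base_between: float = 0.10
    volume_floor_cc: float = 0.1
    n_discard: int = 4  # informational: downstream discards this many volumes

    def __post_init__(self) -> None:
        if self.group_effects is None:
            self.group_effects = default_group_effects(self.n_rois)
        self.validate()

    def validate(self) -> None:
        if set(self.n_per_group) != set(GROUPS):
            raise ValueError(f"n_per_group must have keys {GROUPS}")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("each group needs at least 2 subjects")
        if self.n_rois < len(TARGET_ROI_NAMES):
            raise ValueError("n_rois must cover the 10 target ROIs")
        if self.n_timepoints <= self.n_discard:
            raise ValueError("n_timepoints must exceed the discard count")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        targets = set(default_target_indices(self.n_rois))
        for eff in self.group_effects:
            if not 0 <= eff.roi_index < self.n_rois:
                raise ValueError(f"effect roi_index {eff.roi_index} out of range")
            if eff.kind == "volume_shift" and eff.roi_index not in targets:
                raise ValueError("volume_shift effects must target a subcortical ROI")
        for g in GROUPS:
            params = self.volume_params[g]
            if len(params) != len(TARGET_ROI_NAMES):
                raise ValueError(f"volume_params[{g!r}] must have 10 (mean, sd) pairs")
            if any(sd < 0 for _, sd in params):
                raise ValueError("volume SDs must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_effects"] = [asdict(e) for e in self.group_effects]
        d["n_per_group"] = dict(self.n_per_group)
        d["volume_params"] = {g: [list(p) for p in v]
                              for g, v in self.volume_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        d["group_effects"] = [EffectSpec(**e) for e in d.get("group_effects") or []] \
            if d.get("group_effects") is not None else None
        if "volume_params" in d:
            d["volume_params"] = {g: [tuple(p) for p in v]
                                  for g, v in d["volume_params"].items()}
        return cls(**d)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    timeseries: np.ndarray  # T x R
    volumes: np.ndarray     # len(TARGET_ROI_NAMES), cc

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.timeseries.ndim != 2 or self.timeseries.shape[0] < 2:
            raise ValueError("timeseries must be a T x R matrix with T >= 2")
        if not np.isfinite(self.timeseries).all() or not np.isfinite(self.volumes).all():
            raise ValueError("missing/non-finite values in subject record")
        if (self.volumes <= 0).any():
            raise ValueError("volumes must be positive")


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    roi_names: list[str]
    target_roi_indices: list[int]
    config: CohortConfig | None = None

    def __post_init__(self) -> None:
        r = len(self.roi_names)
        for s in self.subjects:
            if s.timeseries.shape[1] != r:
                raise ValueError(f"subject {s.subject_id}: ROI count mismatch")
        if len(set(self.target_roi_indices)) != len(self.target_roi_indices):
            raise ValueError("target_roi_indices must be distinct")
        if any(not 0 <= i < r for i in self.target_roi_indices):
            raise ValueError("target_roi_indices out of range")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def target_roi_names(self) -> list[str]:
        return [self.roi_names[i] for i in self.target_roi_indices]

    def volumes_matrix(self) -> np.ndarray:
        """subjects x target-ROIs volume matrix (cc)."""
        return np.vstack([s.volumes for s in self.subjects])

    # ---- serialization (manifest + per-subject time-series CSVs) ----

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        (path / "timeseries").mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"subject_id": self.subject_ids,
                      "group": [s.group for s in self.subjects]}
                     ).to_csv(path / "manifest.csv", index=False)
        pd.DataFrame(self.volumes_matrix(), index=self.subject_ids,
                     columns=self.target_roi_names
                     ).rename_axis("subject_id").to_csv(path / "volumes.csv")
        for s in self.subjects:
            pd.DataFrame(s.timeseries, columns=self.roi_names).to_csv(
                path / "timeseries" / f"{s.subject_id}.csv", index=False)
        sidecar = {"roi_names": self.roi_names,
                   "target_roi_indices": self.target_roi_indices,
                   "config": self.config.to_dict() if self.config else None}
        (path / "cohort.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        sidecar = json.loads((path / "cohort.json").read_text())
        manifest = pd.read_csv(path / "manifest.csv")
        volumes = pd.read_csv(path / "volumes.csv", index_col="subject_id")
        subjects = []
        for sid, group in zip(manifest["subject_id"], manifest["group"]):
            ts = pd.read_csv(path / "timeseries" / f"{sid}.csv").to_numpy()
            subjects.append(SubjectRecord(sid, group, ts, volumes.loc[sid].to_numpy()))
        cfg = sidecar.get("config")
        return cls(subjects, sidecar["roi_names"], sidecar["target_roi_indices"],
                   CohortConfig.from_dict(cfg) if cfg else None)


# --------------------------------------------------------------------------
# covariance construction

def base_covariance(n_rois: int, n_blocks: int = 6, within: float = 0.45,
                    between: float = 0.10) -> np.ndarray:
    """Two-level block correlation matrix (unit diagonal, PSD by construction).

    ROI i belongs to community ``i % n_blocks``; correlation is ``within``
    inside a community and ``between`` across communities.  The matrix is a
    non-negative combination of the all-ones matrix, the block-indicator
    matrix and the identity, hence PSD whenever
    ``0 <= between <= within <= 1``.
    """
    if not 0 <= between <= within < 1:
        raise ValueError("need 0 <= between <= within < 1")
    blocks = np.arange(n_rois) % n_blocks
    same = (blocks[:, None] == blocks[None, :]).astype(float)
    cov = between + (within - between) * same
    np.fill_diagonal(cov, 1.0)
    return cov


def _nearest_psd_corr(mat: np.ndarray, max_iter: int = 500,
                      tol: float = -1e-12) -> np.ndarray:
    """Alternating projection onto PSD matrices and unit-diagonal matrices."""
    out = (mat + mat.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(out)
        if w[0] >= tol and np.allclose(np.diag(out), 1.0, atol=1e-12):
            return out
        out = (v * np.clip(w, 0.0, None)) @ v.T
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    return out


def build_group_covariance(base_cov: np.ndarray,
                           effects: Sequence[EffectSpec]) -> np.ndarray:
    """Apply hub effects for one group to the base covariance.

    Off-diagonal row/column entries of each targeted ROI are scaled by the
    effect magnitude; the result is then projected back to the nearest
    positive-semidefinite matrix with unit diagonal (Higham-style alternating
    projection), so any PSD violation introduced by the scaling is repaired
    deterministically.
    """
    base_cov = np.asarray(base_cov, dtype=float)
    if not np.allclose(base_cov, base_cov.T, atol=1e-10):
        raise ValueError("base covariance must be symmetric")
    w_min = float(np.linalg.eigvalsh(base_cov)[0])
    if w_min < -1e-10:
        raise ValueError(f"base covariance is not PSD (smallest eigenvalue {w_min:.3e})")
    cov = base_cov.copy()
    scaled = False
    for eff in effects:
        if eff.kind not in ("hub_weaken", "hub_strengthen"):
            continue
        i = eff.roi_index
        off = np.ones(cov.shape[0], dtype=bool)
        off[i] = False
        cov[i, off] *= eff.magnitude
        cov[off, i] *= eff.magnitude
        if eff.magnitude != 1.0:
            scaled = True
    if scaled:
        cov = _nearest_psd_corr(cov)
    return cov


# --------------------------------------------------------------------------
# sampling

def _matrix_sqrt(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v * np.sqrt(np.clip(w, 0.0, None))


def sample_timeseries(cov: np.ndarray, n_timepoints: int,
                      seed: int | np.random.Generator = 0,
                      *, _sqrt: np.ndarray | None = None) -> np.ndarray:
    """T x R draw with i.i.d. rows from N(0, cov)."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    left = _sqrt if _sqrt is not None else _matrix_sqrt(np.asarray(cov, dtype=float))
    z = rng.standard_normal((n_timepoints, left.shape[0]))
    return z @ left.T


def sample_volumes(params: Sequence[tuple[float, float]],
                   seed: int | np.random.Generator = 0,
                   floor_cc: float = 0.1) -> np.ndarray:
    """Independent normal draws per region, truncated below at ``floor_cc``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.array([m for m, _ in params], dtype=float)
    sds = np.array([s for _, s in params], dtype=float)
    if (sds < 0).any():
        raise ValueError("volume SDs must be >= 0")
    draws = means + sds * rng.standard_normal(len(means))
    return np.maximum(draws, floor_cc)


def _subject_seed_sequence(master_seed: int, subject_id: str) -> np.random.SeedSequence:
    # stable across processes: hash the subject id, not Python's salted hash()
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.SeedSequence([master_seed, sub])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample a full cohort, reproducibly from ``config.seed``.

    Each subject gets an independent random substream keyed by a stable hash
    of its subject id, so adding or removing subjects never perturbs the data
    of the others.
    """
    config.validate()
    roi_names = default_roi_names(config.n_rois)
    base = base_covariance(config.n_rois, config.n_blocks,
                           config.base_within, config.base_between)
    targets = default_target_indices(config.n_rois)
    target_pos = {roi: j for j, roi in enumerate(targets)}

    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        group_fx = [e for e in config.group_effects if e.target_group == group]
        cov = build_group_covariance(base, group_fx)
        sqrt = _matrix_sqrt(cov)
        means = np.array([m for m, _ in config.volume_params[group]])
        for eff in group_fx:
            if eff.kind == "volume_shift":
                means = means.copy()
                means[target_pos[eff.roi_index]] += eff.magnitude
        vparams = list(zip(means, (s for _, s in config.volume_params[group])))
        for i in range(config.n_per_group[group]):
            sid = f"{group}_{i:03d}"
            ts_rng, vol_rng = (np.random.default_rng(s) for s in
                               _subject_seed_sequence(config.seed, sid).spawn(2))
            ts = sample_timeseries(cov, config.n_timepoints, ts_rng, _sqrt=sqrt)
            vols = sample_volumes(vparams, vol_rng, config.volume_floor_cc)
            subjects.append(SubjectRecord(sid, group, ts, vols))
    if not subjects:
        warnings.warn("empty cohort generated")
    return Cohort(subjects, roi_names, targets, config)
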