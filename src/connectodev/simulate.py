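"""Synthetic longitudinal connectome cohorts with known planted effects.

The real cohort behind this analysis (two diagnostic groups, up to three
scanning waves about 18 months apart across ages 9–14) is restricted, so
every pipeline stage is exercised on generated data whose ground truth is
known. The generator emulates the study's design features:

* **phenotypes** — ~85 subjects per group, wave age means near 10.4 / 11.6 /
  13.2 years, monotone dropout, group- and wave-specific head-motion
  distributions, a scanner upgrade at wave 3, medication only in the
  clinical group, and group-specific sex ratios;
* **functional data** — per-scan multivariate-normal time series with a
  modular correlation template, a per-subject perturbation shared across
  waves (which induces within-subject correlation of downstream metrics),
  and planted effects in chosen target regions: a constant group offset of
  the target correlations, or a trajectory divergence in which the target
  correlations drift with age at group-specific rates;
* **structural data** — negative-binomial streamline counts around a sparse
  modular backbone, per-subject gain factors, log-normal node volumes, and
  an injected fraction of spurious low-mean high-dispersion edges so that
  consistency thresholding has real work to do.

All generators are pure functions of (spec, seed). The default parcellation
is 60 regions in 6 modules, a desk-scale stand-in for a 360-region atlas.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import NodeVolumes, RoiTimeSeries, ScanRecord

logger = logging.getLogger("connectodev")

#: Head-motion (mean FD, mm) by group and wave; clinical group moves more at
#: the younger waves, and motion declines with age.
DEFAULT_FD_MEANS = {
    "ADHD": (0.19, 0.16, 0.11),
    "control": (0.18, 0.13, 0.10),
}
DEFAULT_FD_SDS = {
    "ADHD": (0.16, 0.11, 0.06),
    "control": (0.12, 0.09, 0.05),
}
DEFAULT_MALE_FRACTION = {"ADHD": 0.71, "control": 0.56}


@dataclass
class CohortSpec:
    """Design of a synthetic longitudinal cohort."""

    n_per_group: int = 85
    n_waves: int = 3
    wave_age_means: tuple[float, ...] = (10.40, 11.63, 13.24)
    wave_age_sds: tuple[float, ...] = (0.5, 0.5, 0.5)
    dropout_per_wave: float = 0.15
    fd_means: dict = field(default_factory=lambda: dict(DEFAULT_FD_MEANS))
    fd_sds: dict = field(default_factory=lambda: dict(DEFAULT_FD_SDS))
    male_fraction: dict = field(default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    scanner_switch_wave: int = 3
    medication_rate: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_waves < 1:
            raise ValueError("n_per_group and n_waves must be >= 1")
        if len(self.wave_age_means) < self.n_waves or len(self.wave_age_sds) < self.n_waves:
            raise ValueError("need an age mean and sd per wave")
        if not 0 <= self.dropout_per_wave <= 1 or not 0 <= self.medication_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class NetworkTemplate:
    """Modular correlation/count template standing in for cortical covariance."""

    n_regions: int
    module_assignment: np.ndarray
    within_module_r: float = 0.45
    between_module_r: float = 0.12
    structural_backbone: np.ndarray | None = None
    volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape[0] != self.n_regions:
            raise ValueError("module assignment length must equal n_regions")
        if self.structural_backbone is not None:
            b = np.asarray(self.structural_backbone, dtype=float)
            if b.shape != (self.n_regions, self.n_regions):
                raise ValueError("backbone must be N x N")
            if not np.allclose(b, b.T) or np.any(np.diag(b) != 0):
                raise ValueError("backbone must be symmetric with zero diagonal")
            self.structural_backbone = b
        if self.volumes is not None and np.any(np.asarray(self.volumes) <= 0):
            raise ValueError("volumes must be positive")

    @property
    def region_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def base_correlation(self) -> np.ndarray:
        same = self.module_assignment[:, None] == self.module_assignment[None, :]
        c = np.where(same, self.within_module_r, self.between_module_r).astype(float)
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class EffectSpec:
    """A planted group effect on target regions of one modality.

    ``group_offset`` shifts the clinical group's target-region connectivity
    by ``direction * magnitude`` at every age; ``trajectory_divergence``
    makes the shift grow linearly with (age - 9) at ``direction * magnitude``
    per year in the clinical group only, so trajectories diverge.
    Magnitudes are in correlation units (functional) or log-count units
    (structural).
    """

    target_regions: tuple[int, ...]
    modality: str = "functional"
    effect_kind: str = "group_offset"
    magnitude: float = 0.1
    direction: int = 1

    def __post_init__(self) -> None:
        if self.effect_kind not in ("group_offset", "trajectory_divergence"):
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def default_template(
    n_regions: int = 60,
    n_modules: int = 6,
    within_module_r: float = 0.45,
    between_module_r: float = 0.12,
    backbone_within: float = 80.0,
    backbone_between: float = 10.0,
    seed: int = 12345,
) -> NetworkTemplate:
    """Desk-scale modular template: contiguous modules, sparse between-module
    backbone (each module wired to its ring neighbours), log-normal volumes."""
    modules = np.repeat(np.arange(n_modules), int(np.ceil(n_regions / n_modules)))[:n_regions]
    rng = np.random.default_rng(seed)
    backbone = np.zeros((n_regions, n_regions))
    same = modules[:, None] == modules[None, :]
    backbone[same] = backbone_within
    # between-module: connect a few node pairs bridging adjacent modules
    for m in range(n_modules):
        a = np.flatnonzero(modules == m)
        b = np.flatnonzero(modules == (m + 1) % n_modules)
        for _ in range(max(2, len(a) // 3)):
            i, j = rng.choice(a), rng.choice(b)
            backbone[i, j] = backbone[j, i] = backbone_between
    np.fill_diagonal(backbone, 0.0)
    volumes = rng.lognormal(mean=np.log(3000.0), sigma=0.3, size=n_regions)
    return NetworkTemplate(
        n_regions=n_regions,
        module_assignment=modules,
        within_module_r=within_module_r,
        between_module_r=between_module_r,
        structural_backbone=backbone,
        volumes=volumes,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def generate_phenotypes(spec: CohortSpec) -> list[ScanRecord]:
    """Subjects, waves, ages, covariates; reproducible from ``spec.seed``.

    Ages are drawn around the wave means and forced strictly increasing
    within subject; dropout is monotone (a subject who misses a wave stays
    out); the scanner flips to post-upgrade at ``scanner_switch_wave``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ScanRecord] = []
    for group in ("ADHD", "control"):
        male_frac = spec.male_fraction.get(group, 0.5)
        for s in range(spec.n_per_group):
            subject_id = f"{group[:3].lower()}{s:03d}"
            sex = "M" if rng.random() < male_frac else "F"
            medicated_subject = group == "ADHD" and rng.random() < spec.medication_rate
            prev_age = -np.inf
            for w in range(1, spec.n_waves + 1):
                if w > 1 and rng.random() < spec.dropout_per_wave:
                    break  # monotone dropout
                age = rng.normal(spec.wave_age_means[w - 1], spec.wave_age_sds[w - 1])
                age = float(max(age, prev_age + 0.9))
                prev_age = age
                mu = spec.fd_means[group][min(w - 1, len(spec.fd_means[group]) - 1)]
                sd = spec.fd_sds[group][min(w - 1, len(spec.fd_sds[group]) - 1)]
                # log-normal head motion matching the requested mean and sd
                s2 = np.log1p((sd / mu) ** 2)
                fd = float(rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2)))
                records.append(
                    ScanRecord(
                        scan_id=f"{subject_id}_w{w}",
                        subject_id=subject_id,
                        wave=w,
                        age=age,
                        group=group,
                        sex=sex,
                        fd=fd,
                        scanner="post_upgrade" if w >= spec.scanner_switch_wave else "pre_upgrade",
                        medicated=medicated_subject,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Functional time series
# ---------------------------------------------------------------------------


def _nearest_pd_correlation(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues from below and renormalize to unit diagonal."""
    c = (c + c.T) / 2
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < floor:
        logger.debug("eigenvalue clipping triggered (min %.3g)", vals.min())
        vals = np.clip(vals, floor, None)
        c = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _apply_functional_effects(
    c: np.ndarray,
    template: NetworkTemplate,
    effects: Sequence[EffectSpec],
    record: ScanRecord,
) -> np.ndarray:
    """Shift the target regions' between-module correlations.

    Between-module correlations sit near the operating edge threshold, so a
    shift there changes each target's edge probabilities — and hence its
    degree, local efficiency and betweenness after binarization. Shifting
    within-module correlations would barely move the binary topology, since
    those edges are comfortably above threshold already.
    """
    modules = template.module_assignment
    for eff in effects:
        if eff.modality != "functional":
            continue
        if eff.effect_kind == "group_offset":
            shift = eff.direction * eff.magnitude if record.group == "ADHD" else 0.0
        else:  # trajectory_divergence: clinical group drifts with age
            shift = (
                eff.direction * eff.magnitude * (record.age - 9.0)
                if record.group == "ADHD"
                else 0.0
            )
        if shift == 0.0:
            continue
        for t in eff.target_regions:
            partners = np.flatnonzero(modules != modules[t])
            c[t, partners] += shift
            c[partners, t] += shift
    return np.clip(c, -0.99, 0.99)


def generate_functional_timeseries(
    records: Sequence[ScanRecord],
    template: NetworkTemplate,
    effects: Sequence[EffectSpec] = (),
    T: int = 150,
    seed: int = 0,
    subject_sd: float = 0.03,
) -> list[RoiTimeSeries]:
    """Per-scan multivariate-normal BOLD surrogates.

    Each scan's correlation matrix is the modular template, plus a symmetric
    per-subject within-module perturbation (sd ``subject_sd``, constant
    across the subject's waves), plus any planted effects; the result is
    projected to the nearest positive-definite correlation matrix and ``T``
    exchangeable samples are drawn. Bit-reproducible from ``seed``.
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    base = template.base_correlation()
    modules = template.module_assignment
    same = modules[:, None] == modules[None, :]
    np.fill_diagonal(same, False)
    subjects = sorted({r.subject_id for r in records})
    root = np.random.SeedSequence(seed)
    subj_seeds = {s: ss for s, ss in zip(subjects, root.spawn(len(subjects)))}
    out: list[RoiTimeSeries] = []
    labels = template.region_labels
    for rec in sorted(records, key=lambda r: r.scan_id):
        srng = np.random.default_rng(subj_seeds[rec.subject_id])
        bump = float(srng.normal(0.0, subject_sd))
        scan_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(rec.scan_id.encode()), 1))
        )
        c = base.copy()
        c[same] += bump
        c = _apply_functional_effects(c, template, effects, rec)
        c = _nearest_pd_correlation(c)
        chol = np.linalg.cholesky(c)
        data = scan_rng.standard_normal((T, template.n_regions)) @ chol.T
        out.append(RoiTimeSeries(scan_id=rec.scan_id, data=data, region_labels=list(labels)))
    return out


# ---------------------------------------------------------------------------
# Structural counts
# ---------------------------------------------------------------------------


def generate_structural_counts(
    records: Sequence[ScanRecord],
    template: NetworkTemplate,
    effects: Sequence[EffectSpec] = (),
    seed: int = 0,
    spurious_fraction: float = 0.25,
    spurious_mean: float = 2.0,
    backbone_dispersion: float = 20.0,
    spurious_dispersion: float = 0.5,
    subject_sd: float = 0.15,
) -> tuple[dict[str, np.ndarray], NodeVolumes, np.ndarray]:
    """Per-scan streamline-count matrices, node volumes, spurious-edge labels.

    Counts are negative-binomial around ``backbone * subject_gain *
    exp(effect)``. A fixed set of zero-backbone node pairs (a fraction
    ``spurious_fraction`` of the candidate pool) receives low-mean,
    high-dispersion counts each appearing in only some subjects, mimicking
    tractography false positives; the boolean matrix of those pairs is
    returned so simulations can score consistency thresholding against
    labelled truth.
    """
    if template.structural_backbone is None:
        raise ValueError("template has no structural backbone")
    n = template.n_regions
    backbone = template.structural_backbone
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    iu = np.triu_indices(n, k=1)
    zero_pairs = np.flatnonzero(backbone[iu] == 0)
    n_spur = int(round(spurious_fraction * zero_pairs.size))
    spur_idx = rng.choice(zero_pairs, size=n_spur, replace=False)
    spurious = np.zeros((n, n), dtype=bool)
    spurious[iu[0][spur_idx], iu[1][spur_idx]] = True
    spurious |= spurious.T

    subjects = sorted({r.subject_id for r in records})
    gains = {
        s: float(g)
        for s, g in zip(subjects, rng.lognormal(0.0, subject_sd, size=len(subjects)))
    }

    def nb_draw(r_disp: float, mean: np.ndarray, gen: np.random.Generator) -> np.ndarray:
        p = r_disp / (r_disp + mean)
        return gen.negative_binomial(r_disp, p)

    out: dict[str, np.ndarray] = {}
    for rec in sorted(records, key=lambda r: r.scan_id):
        gen = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(rec.scan_id.encode()), 2))
        )
        logadj = np.zeros((n, n))
        for eff in effects:
            if eff.modality != "structural":
                continue
            if eff.effect_kind == "group_offset":
                shift = eff.direction * eff.magnitude if rec.group == "ADHD" else 0.0
            else:
                shift = (
                    eff.direction * eff.magnitude * (rec.age - 9.0)
                    if rec.group == "ADHD"
                    else 0.0
                )
            if shift == 0.0:
                continue
            for t in eff.target_regions:
                logadj[t, :] += shift
                logadj[:, t] += shift
        mean = backbone * gains[rec.subject_id] * np.exp(np.where(backbone > 0, logadj, 0.0))
        counts = np.zeros((n, n))
        pos = backbone > 0
        counts[pos] = nb_draw(backbone_dispersion, mean[pos], gen)
        # spurious edges: present in ~half the subjects, very dispersed
        appear = gen.random((n, n)) < 0.5
        appear = np.triu(appear, 1)
        appear = appear | appear.T
        sp = spurious & appear
        counts[sp] = nb_draw(spurious_dispersion, np.full(sp.sum(), spurious_mean), gen)
        counts = np.triu(counts, 1)
        counts = counts + counts.T
        out[rec.scan_id] = counts
    return out, NodeVolumes(np.asarray(template.volumes)), spurious


def ground_truth_table(effects: Sequence[EffectSpec]) -> pd.DataFrame:
    """Machine-readable answer key: one row per (target region, effect)."""
    rows = [
        {
            "region_index": int(t),
            "modality": eff.modality,
            "effect_kind": eff.effect_kind,
            "direction": eff.direction,
            "magnitude": eff.magnitude,
            "expected_winner": "group" if eff.effect_kind == "group_offset" else "interaction",
        }
        for eff in effects
        for t in eff.target_regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "region_index", "modality", "effect_kind", "direction",
            "magnitude", "expected_winner",
        ],
    )
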