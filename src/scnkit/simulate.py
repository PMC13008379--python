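"""Synthetic multisite volumetric cohorts with known ground truth.

The consortium data this pipeline was designed around (subject-level regional
brain volumes pooled across many scanners) cannot be redistributed, so every
downstream stage is validated on simulated cohorts in which the quantities the
pipeline is supposed to recover are implanted by construction:

* group-specific covariance structure — controls are drawn from a base
  correlation matrix, cases from the same matrix with chosen edge-wise
  correlation shifts (the group ``SC_diff`` the network comparison must find);
* scanner/site effects — region-wise affine maps (additive shift,
  multiplicative scale) applied per site, the batch model ComBat assumes;
* covariate effects — linear age, quadratic age, sex offset and intracranial
  volume (ICV) terms added to each region, which residualization must remove;
* severity links — a symptom score coupled to each case subject's realized
  perturbation of a designated edge, so the individual differential SCN stage
  has a recoverable severity–edge association.

All randomness flows from a single spec-level seed through spawned
:class:`numpy.random.Generator` streams, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "build_base_covariance",
    "implant_edge_effects",
    "generate_cohort",
    "generate_severity",
    "nearest_psd_correlation",
    "uniform_correlation",
]

_PSD_TOL = 1e-8


def uniform_correlation(n_regions: int, r: float) -> np.ndarray:
    """Equicorrelation matrix: unit diagonal, ``r`` everywhere else."""
    if not -1.0 / max(n_regions - 1, 1) <= r < 1.0:
        raise ValueError(f"equicorrelation r={r} is not positive semidefinite for n={n_regions}")
    out = np.full((n_regions, n_regions), float(r))
    np.fill_diagonal(out, 1.0)
    return out


def nearest_psd_correlation(mat: np.ndarray, tol: float = _PSD_TOL) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to a PSD correlation matrix.

    Eigenvalue clipping at zero followed by re-normalization to unit diagonal.
    Returns the repaired matrix and the maximum absolute entry displacement,
    so implanted ground truth stays auditable after repair.
    """
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        repaired = sym.copy()
        np.fill_diagonal(repaired, 1.0)
        return repaired, float(np.abs(repaired - mat).max())
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise ValueError("PSD repair produced a zero-variance region; matrix too degenerate")
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    drift = float(np.abs(repaired - mat).max())
    if np.linalg.eigvalsh(repaired).min() < -tol:
        raise ValueError("matrix not positive semidefinite after repair")
    return repaired, drift


def build_base_covariance(
    n_regions: int,
    blocks: Sequence[tuple[int, float]],
    seed: int | None = None,
    between_r: float = 0.0,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Block-structured base correlation matrix.

    Parameters
    ----------
    n_regions : total number of regions; block sizes must sum to this.
    blocks : sequence of ``(size, within_r)`` — each block is an
        equicorrelated group of regions with within-block correlation
        ``within_r`` (0 <= within_r < 1).
    seed : seed for the optional jitter.
    between_r : correlation between regions of different blocks.
    jitter_sd : SD of symmetric Gaussian noise added off-diagonal before
        PSD repair (0 disables).
    """
    sizes = [int(s) for s, _ in blocks]
    if any(s < 1 for s in sizes):
        raise ValueError("block sizes must be >= 1")
    if sum(sizes) != n_regions:
        raise ValueError(f"block sizes {sizes} sum to {sum(sizes)}, expected n_regions={n_regions}")
    for k, (size, r) in enumerate(blocks):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"block {k} (size={size}): within_r must be in [0, 1), got {r}")
    cov = np.full((n_regions, n_regions), float(between_r))
    start = 0
    for size, r in blocks:
        cov[start : start + size, start : start + size] = r
        start += size
    np.fill_diagonal(cov, 1.0)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter_sd, size=cov.shape)
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        cov = np.clip(cov + noise, -1.0, 1.0)
    try:
        repaired, _ = nearest_psd_correlation(cov)
    except ValueError as err:
        raise ValueError(f"base covariance not PSD-repairable for blocks={list(blocks)}: {err}") from err
    return repaired


def implant_edge_effects(
    cov: np.ndarray,
    effects: Sequence[tuple[int, int, float]],
) -> tuple[np.ndarray, float]:
    """Shift chosen correlation entries by ``delta_r`` and repair to PSD.

    Returns ``(new_cov, max_drift)`` where ``max_drift`` is the largest
    entry displacement introduced by the PSD repair (0 when no repair was
    needed). Raises if any target entry would leave [-1, 1].
    """
    out = np.array(cov, dtype=float, copy=True)
    for i, j, delta in effects:
        if i == j:
            raise ValueError(f"edge ({i},{j}) is a diagonal entry; only off-diagonal effects allowed")
        new = out[i, j] + delta
        if not -1.0 <= new <= 1.0:
            raise ValueError(f"edge ({i},{j}): correlation {out[i, j]} + {delta} leaves [-1, 1]")
        out[i, j] = new
        out[j, i] = new
    shifted = out.copy()
    repaired, _ = nearest_psd_correlation(out)
    drift = float(np.abs(repaired - shifted).max())
    return repaired, drift


@dataclass
class CohortSpec:
    """Full description of a simulated multisite cohort.

    ``case_edge_effects`` entries are ``(i, j, delta_r)`` region indices into
    ``region_labels``. ``site_effects`` maps site label to
    ``(additive, multiplicative)`` per-region arrays (or scalars).
    ``covariate_effects`` holds per-region (or scalar) coefficients under keys
    ``age``, ``age2``, ``sex``, ``icv``; age is centered at 40 years and ICV at
    its population mean before the coefficients apply. ``severity_link`` is
    ``(i, j, link, noise_sd)``: case severity is coupled to the subject's
    realized perturbation of edge (i, j) with correlation
    link / sqrt(link^2 + noise_sd^2).
    """

    n_control: int
    n_case: int
    region_labels: Sequence[str]
    base_covariance: np.ndarray
    case_edge_effects: Sequence[tuple[int, int, float]] = ()
    site_labels: Sequence[str] = ("site1",)
    site_effects: dict | None = None
    covariate_effects: dict | None = None
    severity_link: tuple[int, int, float, float] | None = None
    region_mean: float | np.ndarray = 1000.0
    region_sd: float | np.ndarray = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("subject counts must be >= 0")
        self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        p = len(self.region_labels)
        if self.base_covariance.shape != (p, p):
            raise ValueError(
                f"base_covariance shape {self.base_covariance.shape} does not match "
                f"{p} region labels"
            )
        if not np.allclose(self.base_covariance, self.base_covariance.T):
            raise ValueError("base_covariance must be symmetric")
        if not np.allclose(np.diag(self.base_covariance), 1.0):
            raise ValueError("base_covariance must have unit diagonal")
        if np.linalg.eigvalsh(self.base_covariance).min() < -_PSD_TOL:
            raise ValueError("base_covariance is not positive semidefinite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    control_covariance: np.ndarray
    case_covariance: np.ndarray
    perturbed_edges: list[tuple[str, str, float]]
    latent_perturbation: pd.Series  # per case subject, NaN-free
    site_effects: dict
    severity_edge: tuple[str, str] | None = None
    repair_drift: float = 0.0

    def to_dict(self) -> dict:
        return {
            "control_covariance": self.control_covariance.tolist(),
            "case_covariance": self.case_covariance.tolist(),
            "perturbed_edges": [[a, b, float(d)] for a, b, d in self.perturbed_edges],
            "latent_perturbation": {k: float(v) for k, v in self.latent_perturbation.items()},
            "site_effects": {
                s: {"additive": np.asarray(a).tolist(), "multiplicative": np.asarray(m).tolist()}
                for s, (a, m) in self.site_effects.items()
            },
            "severity_edge": list(self.severity_edge) if self.severity_edge else None,
            "repair_drift": self.repair_drift,
        }


METADATA_COLUMNS = ["subject_id", "site", "group", "age", "sex", "icv", "severity"]

_AGE_CENTER = 40.0
_ICV_MEAN = 1.45e6
_ICV_SD = 1.4e5


def _sample_mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    if w.min() < -_PSD_TOL:
        raise ValueError("degenerate covariance: negative eigenvalue before sampling")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, cov.shape[0])) @ factor.T


def generate_severity(
    latent: np.ndarray,
    link: float,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    mode: str = "linear",
) -> np.ndarray:
    """Map per-subject latent perturbation scores to [0, 1] symptom scores.

    The latent is standardized, mixed with Gaussian noise as
    ``raw = link*z + noise_sd*eps``, and mapped onto the unit interval by a
    clamped linear map spanning ±4 SD of ``raw`` (default) or a logistic
    squash. With ``link=r`` and ``noise_sd=sqrt(1-r^2)`` the population
    correlation between latent and score is ~``r`` (the clamp binds only in
    the extreme tails).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent scores must be finite")
    sd = latent.std()
    z = (latent - latent.mean()) / sd if sd > 0 else np.zeros_like(latent)
    raw = link * z + noise_sd * rng.standard_normal(latent.shape)
    scale = float(np.hypot(link, noise_sd))
    if scale == 0.0:
        return np.full(latent.shape, 0.5)
    if mode == "linear":
        return np.clip(0.5 + raw / (8.0 * scale), 0.0, 1.0)
    if mode == "logistic":
        return 1.0 / (1.0 + np.exp(-raw / scale))
    raise ValueError(f"unknown severity mode {mode!r}")


def _per_region(value, p: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(p, float(arr))
    if arr.shape != (p,):
        raise ValueError(f"per-region value has shape {arr.shape}, expected ({p},)")
    return arr


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort feature table plus its ground truth from a spec.

    One row per subject. Region volumes are drawn from the group-specific
    multivariate normal, scaled/shifted by the subject's site effects, then
    covariate effects are added; metadata columns are complete. Controls carry
    ``NaN`` severity (symptom scores exist for cases only).
    """
    p = len(spec.region_labels)
    labels = list(spec.region_labels)
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_draw, rng_demo, rng_sev, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    del rng_cov  # reserved stream: keeps other streams stable if cov becomes random

    control_cov = spec.base_covariance
    case_cov, drift = implant_edge_effects(control_cov, spec.case_edge_effects)
    perturbed = [
        (labels[i], labels[j], float(case_cov[i, j] - control_cov[i, j]))
        for i, j, _ in spec.case_edge_effects
        if case_cov[i, j] != control_cov[i, j]
    ]

    n = spec.n_control + spec.n_case
    group = np.array(["control"] * spec.n_control + ["case"] * spec.n_case)
    z = np.empty((n, p))
    if spec.n_control:
        z[: spec.n_control] = _sample_mvn(rng_draw, control_cov, spec.n_control)
    if spec.n_case:
        z[spec.n_control :] = _sample_mvn(rng_draw, case_cov, spec.n_case)

    subject_id = np.array([f"sub-{k:05d}" for k in range(n)])
    site = np.array(spec.site_labels, dtype=object)[rng_demo.integers(0, len(spec.site_labels), n)] \
        if n else np.array([], dtype=object)
    age = rng_demo.uniform(18.0, 65.0, n)
    sex = rng_demo.integers(0, 2, n).astype(float)
    icv = rng_demo.normal(_ICV_MEAN, _ICV_SD, n)

    mean = _per_region(spec.region_mean, p)
    sd = _per_region(spec.region_sd, p)
    vols = mean + sd * z
    if spec.noise_sd > 0 and n:
        vols = vols + spec.noise_sd * rng_noise.standard_normal((n, p))

    site_fx = {}
    for s in spec.site_labels:
        add, mult = (spec.site_effects or {}).get(s, (0.0, 1.0))
        site_fx[s] = (_per_region(add, p), _per_region(mult, p))
    if n:
        for s, (add, mult) in site_fx.items():
            rows = site == s
            vols[rows] = vols[rows] * mult + add

    cov_fx = spec.covariate_effects or {}
    if n and cov_fx:
        a = _per_region(cov_fx.get("age", 0.0), p)
        a2 = _per_region(cov_fx.get("age2", 0.0), p)
        sx = _per_region(cov_fx.get("sex", 0.0), p)
        iv = _per_region(cov_fx.get("icv", 0.0), p)
        da = age - _AGE_CENTER
        vols = vols + np.outer(da, a) + np.outer(da**2, a2) + np.outer(sex, sx) \
            + np.outer(icv - _ICV_MEAN, iv)

    severity = np.full(n, np.nan)
    latent = pd.Series(dtype=float)
    sev_edge = None
    if spec.n_case:
        case_rows = slice(spec.n_control, n)
        if spec.severity_link is not None:
            i, j, link, noise_sd = spec.severity_link
            sev_edge = (labels[i], labels[j])
            r0 = control_cov[i, j]
            zi, zj = z[case_rows, i], z[case_rows, j]
            # influence-function value of the edge correlation for one added
            # subject: what the subject does to the control-group edge
            lat = zi * zj - r0 * (zi**2 + zj**2) / 2.0
            severity[case_rows] = generate_severity(lat, link, noise_sd, rng_sev)
            latent = pd.Series(lat, index=subject_id[case_rows])
        else:
            severity[case_rows] = rng_sev.uniform(0.0, 1.0, spec.n_case)
            latent = pd.Series(np.zeros(spec.n_case), index=subject_id[case_rows])

    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "site": site,
            "group": group,
            "age": age,
            "sex": sex,
            "icv": icv,
            "severity": severity,
        }
    )
    for k, lab in enumerate(labels):
        table[lab] = vols[:, k] if n else np.array([], dtype=float)

    truth = GroundTruth(
        control_covariance=control_cov,
        case_covariance=case_cov,
        perturbed_edges=perturbed,
        latent_perturbation=latent,
        site_effects=site_fx,
        severity_edge=sev_edge,
        repair_drift=drift,
    )
    return table, truth
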