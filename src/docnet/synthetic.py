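"""Synthetic resting-state cohorts with controlled connectivity structure.

Real disorders-of-consciousness fMRI cohorts are not publicly shareable, so
this module generates three-group cohorts (healthy controls NC, minimally
conscious state MCS, vegetative state VS) of 90-region ROI time series whose
derived Fisher-z connectivity reproduces the group-level statistical
structure the downstream analysis assumes: group-averaged upper-triangle
z means of roughly 0.31 (NC), 0.22 (MCS) and 0.21 (VS), a modular base
connectome, and configurable regional effects (e.g. frontoparietal
reduction, caudate/thalamus elevation in patients).

The generative model, per group:

1.  A block-modular target z-matrix is built whose off-diagonal entries have
    exactly the requested mean and (approximately) the requested spread,
    split between a within/between-module separation and i.i.d. edge noise.
2.  Regional effect factors multiply z rows/columns of named region sets.
3.  The back-transformed correlation matrix ``r = tanh(z)`` is projected to
    the nearest positive-definite correlation matrix (eigenvalue clipping).
4.  Each subject jitters the group z-matrix element-wise, re-projects, and
    draws a stationary Gaussian time series, optionally band-limited with a
    temporal Gaussian kernel (emulating 0.01-0.1 Hz filtering at TR = 2 s).

Everything is a pure function of :class:`CohortSpec` (identical seed gives
a bitwise-identical cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CohortSpec",
    "SubjectTimeSeries",
    "default_effect_map",
    "build_group_covariance",
    "simulate_subject",
    "generate_cohort",
    "aal90_labels",
]

GROUPS = ("NC", "MCS", "VS")

# Fraction of the requested z-entry variance carried by the modular
# within/between-block separation; the rest is i.i.d. edge noise.
_MODULAR_VARIANCE_SHARE = 0.5


def aal90_labels(n_regions: int = 90) -> list[str]:
    """Region labels: paired left/right names in atlas order.

    Real AAL names are not required by any computation; labels are plumbing
    used to key nodal features, so synthetic cohorts use systematic names
    ``R001.L, R001.R, ...`` with the left/right alternation of AAL90.
    """
    labels = []
    for i in range(n_regions):
        side = "L" if i % 2 == 0 else "R"
        labels.append(f"R{i // 2 + 1:03d}.{side}")
    return labels


def _default_region_set(n_regions: int, which: str) -> tuple[int, ...]:
    """Index sets standing in for anatomical systems on the synthetic atlas.

    ``frontoparietal``: 12 regions spread over the first two modules.
    ``subcortical``: 4 regions (caudate/thalamus stand-ins).
    """
    if which == "frontoparietal":
        idx = np.linspace(0, n_regions // 2 - 1, 12).round().astype(int)
    elif which == "subcortical":
        idx = np.linspace(n_regions // 2, n_regions - 1, 4).round().astype(int)
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown region set {which!r}")
    return tuple(int(i) for i in np.unique(idx))


def default_effect_map(n_regions: int = 90) -> dict[str, list[tuple[tuple[int, ...], float]]]:
    """Default per-group regional effects.

    Patient groups carry a modest frontoparietal connectivity reduction and
    a small caudate/thalamus elevation, mirroring the regional reorganisation
    the analysis is meant to detect. Controls carry none. Factors multiply
    Fisher-z rows/columns of the listed regions.
    """
    fp = _default_region_set(n_regions, "frontoparietal")
    sub = _default_region_set(n_regions, "subcortical")
    return {
        "NC": [],
        "MCS": [(fp, 0.90), (sub, 1.15)],
        "VS": [(fp, 0.85), (sub, 1.15)],
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic three-group cohort.

    Defaults mirror the study conditions: 90 AAL regions, 200 usable
    volumes (210 acquired minus 10 discarded), group sizes NC 30 / MCS 19 /
    VS 40, and group-averaged Fisher-z means 0.31 / 0.22 / 0.21 with
    spreads 0.18 / 0.14 / 0.14.
    """

    n_regions: int = 90
    n_timepoints: int = 200
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 30, "MCS": 19, "VS": 40}
    )
    target_mean_z: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 0.31, "MCS": 0.22, "VS": 0.21}
    )
    target_sd_z: Mapping[str, float] = field(
        default_factory=lambda: {"NC": 0.18, "MCS": 0.14, "VS": 0.14}
    )
    effect_map: Mapping[str, Sequence[tuple[tuple[int, ...], float]]] | None = None
    n_modules: int = 4
    subject_jitter_sd: float = 0.06
    smoothing_sd: float = 1.0  # temporal Gaussian kernel SD, in TR units; 0 = off
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be at least 3")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g} must be nonnegative")
        for g, m in self.target_mean_z.items():
            if not (0.0 <= m < 1.0):
                raise ValueError(f"target_mean_z[{g}] must be in [0, 1)")
        for g, s in self.target_sd_z.items():
            if s < 0:
                raise ValueError(f"target_sd_z[{g}] must be nonnegative")
        if self.effect_map is not None:
            for g, entries in self.effect_map.items():
                for regions, factor in entries:
                    if factor <= 0:
                        raise ValueError(
                            f"effect factor for group {g}, regions {regions} "
                            "must be positive"
                        )
                    if any(r < 0 or r >= self.n_regions for r in regions):
                        raise ValueError(
                            f"effect_map for group {g} names regions outside "
                            f"0..{self.n_regions - 1}: {regions}"
                        )

    def effects_for(self, group: str) -> Sequence[tuple[tuple[int, ...], float]]:
        if self.effect_map is None:
            return default_effect_map(self.n_regions).get(group, [])
        return self.effect_map.get(group, [])


@dataclass
class SubjectTimeSeries:
    """One subject's region x time signal matrix with group label."""

    subject_id: str
    group: str
    data: np.ndarray  # (n_regions, n_timepoints)
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D region x time matrix")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("row count must equal label count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if np.any(self.data.std(axis=1) == 0):
            bad = [
                self.region_labels[i]
                for i in np.flatnonzero(self.data.std(axis=1) == 0)
            ]
            raise ValueError(f"zero-variance region(s): {bad}")


def _module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module membership, deterministic."""
    return (np.arange(n_regions) * n_modules) // n_regions


def _nearest_correlation(A: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalised
    to 1 (one pass; the perturbation is small for near-PSD inputs).
    """
    A = (A + A.T) / 2.0
    w, V = np.linalg.eigh(A)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise np.linalg.LinAlgError("projection produced a degenerate diagonal")
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def _base_z_matrix(spec: CohortSpec, group: str, rng: np.random.Generator) -> np.ndarray:
    """Block-modular z-matrix with exact target mean over off-diagonals."""
    n = spec.n_regions
    mu = spec.target_mean_z[group]
    sd = spec.target_sd_z[group]
    if mu == 0.0:
        # Degenerate zero-connectivity spec: no structure at all.
        return np.zeros((n, n))

    modules = _module_assignment(n, spec.n_modules)
    within = modules[:, None] == modules[None, :]
    triu = np.triu_indices(n, k=1)
    f = within[triu].mean()  # fraction of within-module pairs

    var_mod = _MODULAR_VARIANCE_SHARE * sd**2
    var_noise = sd**2 - var_mod
    # Two-level design with exact mean mu and modular variance var_mod:
    # z_within = mu + s(1-f), z_between = mu - s*f, Var = s^2 f(1-f).
    s = np.sqrt(var_mod / (f * (1.0 - f))) if 0.0 < f < 1.0 else 0.0
    Z = np.where(within, mu + s * (1.0 - f), mu - s * f)

    noise = rng.normal(0.0, np.sqrt(var_noise), size=(n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)
    Z = Z + noise
    np.fill_diagonal(Z, 0.0)
    return Z


def _apply_effects(
    Z: np.ndarray,
    effects: Sequence[tuple[Sequence[int], float]],
) -> np.ndarray:
    """Multiply z rows/columns of each region set by its factor."""
    mult = np.ones(Z.shape[0])
    for regions, factor in effects:
        mult[list(regions)] *= factor
    return Z * np.outer(mult, mult)


def _calibrate_z(
    Z: np.ndarray, mu: float, sd: float, max_iter: int = 80, tol: float = 1e-4
) -> np.ndarray:
    """Alternate PD projection with z-moment restoration.

    Projection onto the positive-definite correlation matrices shrinks and
    shifts the Fisher-z entries; an affine correction in z-space restores
    the target mean/SD, and the alternation converges to a PD correlation
    matrix whose upper-triangle z moments match the targets.
    """
    n = Z.shape[0]
    iu = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        R = np.tanh(Z)
        np.fill_diagonal(R, 1.0)
        R = _nearest_correlation(R)
        Zp = np.arctanh(np.clip(R, -1 + 1e-12, 1 - 1e-12))
        np.fill_diagonal(Zp, 0.0)
        v = Zp[iu]
        m0, s0 = v.mean(), v.std()
        if abs(m0 - mu) < tol and (sd == 0 or abs(s0 - sd) < tol):
            return Zp
        w = (v - m0) * (sd / max(s0, 1e-12)) + mu
        Z = np.zeros_like(Zp)
        Z[iu] = w
        Z = Z + Z.T
    return Zp


def build_group_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Group-level correlation matrix whose Fisher-z off-diagonals hit the target.

    The modular base z-matrix is calibrated by alternating positive-definite
    projection with z-moment restoration, so the returned matrix is a
    symmetric positive-definite correlation matrix whose upper-triangle
    Fisher-z mean matches ``target_mean_z[group]`` (within 0.02; in practice
    to ~1e-4 before the regional effects are applied). Effect factors then
    multiply z rows/columns of their region sets, followed by one final
    projection. Raises if an effect entry drives the projection into a
    degenerate diagonal.
    """
    if group not in spec.group_sizes:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0, GROUPS.index(group)])
    )
    Z = _base_z_matrix(spec, group, rng)
    mu = spec.target_mean_z[group]
    if mu != 0.0:
        Z = _calibrate_z(Z, mu, spec.target_sd_z[group])
    effects = spec.effects_for(group)
    Z = _apply_effects(Z, effects)
    R = np.tanh(Z)
    np.fill_diagonal(R, 1.0)
    try:
        return _nearest_correlation(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"group {group}: covariance not positive definite after projection; "
            f"offending effect_map entries: {list(effects)}"
        ) from exc


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    *,
    subject_id: str = "sub-000",
    group: str = "NC",
    region_labels: Sequence[str] | None = None,
    smoothing_sd: float = 0.0,
) -> SubjectTimeSeries:
    """Draw a stationary Gaussian time series with the given covariance.

    A Gaussian temporal kernel (``smoothing_sd`` in sample units) is applied
    identically to every region, band-limiting the spectra the way slow-band
    filtering does; because the same linear filter acts on all channels, the
    zero-lag correlation structure is preserved in expectation.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or not np.allclose(cov, cov.T):
        raise ValueError("cov must be square symmetric")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate (non-positive-definite) covariance") from exc
    X = L @ rng.standard_normal((n, n_timepoints))
    if smoothing_sd > 0:
        X = ndimage.gaussian_filter1d(X, smoothing_sd, axis=1, mode="reflect")
    labels = list(region_labels) if region_labels is not None else aal90_labels(n)
    return SubjectTimeSeries(subject_id=subject_id, group=group, data=X,
                             region_labels=labels)


def generate_cohort(spec: CohortSpec) -> list[SubjectTimeSeries]:
    """Generate the full three-group cohort described by ``spec``.

    Subject-level covariances are Wishart draws centred on the group
    covariance, normalised back to correlation matrices — positive
    definite by construction, with between-subject z variability of
    roughly ``spec.subject_jitter_sd`` per entry (the Wishart degrees of
    freedom are set to ``1/sd^2 + 3``, the Fisher-z variance relation).
    """
    labels = aal90_labels(spec.n_regions)
    cohort: list[SubjectTimeSeries] = []
    for group in GROUPS:
        n_subj = spec.group_sizes.get(group, 0)
        if n_subj == 0:
            continue
        cov = build_group_covariance(spec, group)
        L = np.linalg.cholesky(cov)
        gi = GROUPS.index(group)
        for k in range(n_subj):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 1, gi, k])
            )
            if spec.subject_jitter_sd > 0:
                nu = max(
                    spec.n_regions + 2,
                    int(round(1.0 / spec.subject_jitter_sd**2 + 3)),
                )
                G = L @ rng.standard_normal((spec.n_regions, nu))
                W = G @ G.T / nu
                d = np.sqrt(np.diag(W))
                cov_s = W / np.outer(d, d)
                np.fill_diagonal(cov_s, 1.0)
                cov_s = (cov_s + cov_s.T) / 2.0
            else:
                cov_s = cov
            cohort.append(
                simulate_subject(
                    cov_s,
                    spec.n_timepoints,
                    rng,
                    subject_id=f"sub-{group}-{k:03d}",
                    group=group,
                    region_labels=labels,
                    smoothing_sd=spec.smoothing_sd,
                )
            )
    return cohort
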