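"""Synthetic multi-site cohort generator with known gradient geometry.

The generator plants a two-dimensional latent gradient geometry on a spherical
parcel scheme, draws per-subject fMRI-like time series whose population
covariance decays with distance in that latent space, and layers on exactly the
nuisance and effect structure the downstream pipeline is meant to handle:

* group effects — network mean shifts per gradient, per-network dispersion
  scaling, global range scaling;
* site effects — a multiplicative kernel-amplitude scale (acting on the time
  series) and an additive Fisher-z offset injected at the FC-edge level;
* subject noise — jitter of the latent coordinates;
* clinical scores — noisy linear readouts of each subject's planted
  differentiation metrics, with missing-at-random holes.

Everything is deterministic given the config and its seed: per-subject random
streams are spawned from a single root SeedSequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scheme import ParcelScheme, make_parcel_scheme

GROUPS = ("HC", "ROP", "ROD", "CHR-P")

#: Full-scale group sizes; a cohort is generated at ``scale`` times these.
FULL_GROUP_SIZES = {"HC": 376, "ROP": 243, "ROD": 212, "CHR-P": 240}


@dataclass(frozen=True)
class GroupEffect:
    """Planted group-level deviations from the base gradient geometry.

    mean_shift maps (network, gradient index 1 or 2) -> additive shift of that
    network's latent coordinates on that gradient; dispersion_scale maps
    network -> multiplicative scaling of its spread about its own mean (must be
    > 0); range_scale scales each latent column globally (shrinks the gradient
    range). Shifts are applied last, so a configured shift moves the network
    mean by exactly that amount relative to the no-shift configuration.
    """

    mean_shift: dict = field(default_factory=dict)  # {(network, g): shift}
    dispersion_scale: dict = field(default_factory=dict)  # {network: scale > 0}
    range_scale: tuple = (1.0, 1.0)


@dataclass(frozen=True)
class SiteEffect:
    """Scanner-site nuisance: kernel amplitude scale and additive FC offset."""

    amp_scale: float = 1.0
    fc_offset: float = 0.0


@dataclass(frozen=True)
class GroundTruth:
    """Planted geometry and effect structure of a synthetic cohort."""

    base_latent: np.ndarray  # (P, 2), zero-mean columns
    group_latent: dict  # group -> (P, 2)
    group_effects: dict  # group -> GroupEffect
    site_effects: dict  # site -> SiteEffect
    noise_sd: float


def plant_ground_truth(
    scheme: ParcelScheme,
    group_effects: dict | None = None,
    site_effects: dict | None = None,
    noise_sd: float = 0.05,
    g1_scale: float = 1.0,
    g2_scale: float = 0.8,
    seed: int = 0,
) -> GroundTruth:
    """Plant smooth two-gradient geometry plus group/site effect structure.

    The base latent coordinates come from a Lambert equal-area projection of
    each hemisphere onto a disk (the right hemisphere mirrored onto the left
    before projecting, so homotopic parcels share latent positions). The
    projection is smooth over the sphere and places parcels with uniform density
    in latent space, which keeps the embedding's leading eigenfunctions close to
    linear in the planted axes — the planted geometry is then identifiable from
    the recovered gradients. Gradient 1 follows the z axis (the axis along which
    networks band, so network structure is expressed on g1), gradient 2 the y
    axis, scaled so g1 dominates; columns are zero-meaned. Latent dimensionality
    is fixed at 2: downstream embeddings analyze exactly two gradients and any
    further components carry only noise.
    """
    group_effects = dict(group_effects or {})
    nets = set(scheme.networks)
    for grp, eff in group_effects.items():
        for (net, g) in eff.mean_shift:
            if net not in nets:
                raise ValueError(f"unknown network {net!r} in mean_shift for {grp!r}")
            if g not in (1, 2):
                raise ValueError(f"gradient index must be 1 or 2, got {g}")
        for net, s in eff.dispersion_scale.items():
            if net not in nets:
                raise ValueError(f"unknown network {net!r} in dispersion_scale for {grp!r}")
            if s <= 0:
                raise ValueError(f"dispersion scale must be > 0, got {s} for {net!r}")

    cent = scheme.centroids.copy()
    cent[:, 0] = -np.abs(cent[:, 0])  # mirror right hemisphere onto the left
    # Lambert equal-area projection about the (-1, 0, 0) pole
    factor = np.sqrt(2.0 / (1.0 - cent[:, 0]))
    base = np.column_stack(
        [g1_scale * factor * cent[:, 2], g2_scale * factor * cent[:, 1]]
    )
    base = base - base.mean(axis=0, keepdims=True)

    group_latent = {}
    for grp in GROUPS:
        eff = group_effects.get(grp, GroupEffect())
        lat = base.copy()
        for net, s in eff.dispersion_scale.items():
            idx = scheme.network_indices(net)
            mu = lat[idx].mean(axis=0)
            lat[idx] = mu + s * (lat[idx] - mu)
        lat = lat * np.asarray(eff.range_scale, dtype=float)
        for (net, g), shift in eff.mean_shift.items():
            lat[scheme.network_indices(net), g - 1] += shift
        group_latent[grp] = lat
    return GroundTruth(
        base_latent=base,
        group_latent=group_latent,
        group_effects={g: group_effects.get(g, GroupEffect()) for g in GROUPS},
        site_effects=dict(site_effects or {}),
        noise_sd=noise_sd,
    )


def latent_covariance(
    latent: np.ndarray,
    amp: float = 1.0,
    lengthscale: float = 0.5,
    nugget: float = 0.05,
) -> np.ndarray:
    """Squared-exponential covariance over latent positions plus a diagonal nugget.

    K = amp * exp(-d^2 / (2 l^2)) + nugget * I. The nugget keeps K strictly
    positive definite and bounds the attainable correlation at
    amp / (amp + nugget) — parcels sharing a latent position are correlated but
    not identical, as in real data.
    """
    d = cdist(latent, latent)
    return amp * np.exp(-(d**2) / (2.0 * lengthscale**2)) + nugget * np.eye(len(latent))


def population_correlation(latent, amp=1.0, lengthscale=0.5, nugget=0.05) -> np.ndarray:
    """Population Pearson correlation implied by the kernel."""
    k = latent_covariance(latent, amp, lengthscale, nugget)
    s = np.sqrt(np.diag(k))
    return k / np.outer(s, s)


def synthesize_timeseries(
    latent: np.ndarray,
    n_timepoints: int = 200,
    amp: float = 1.0,
    lengthscale: float = 0.5,
    nugget: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Draw a (timepoints, parcels) Gaussian series with the latent-space kernel.

    Timepoints are i.i.d. (no temporal autocorrelation is modelled); 200
    timepoints matches a typical ~10-minute resting-state acquisition at a
    3-second repetition time.
    """
    if n_timepoints < 10:
        raise ValueError(f"n_timepoints must be >= 10, got {n_timepoints}")
    k = latent_covariance(latent, amp, lengthscale, nugget)
    try:
        chol = np.linalg.cholesky(k)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "covariance kernel is not positive definite; increase the nugget "
            f"parameter (got nugget={nugget})"
        ) from err
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, len(latent)))
    return z @ chol.T


@dataclass(frozen=True)
class ClinicalSpec:
    """One clinical score: intercept + sum(coef * planted metric) + noise.

    ``loadings`` maps a metric key — ``nm_g{1,2}_<net>``, ``wd_<net>`` or
    ``range_g{1,2}`` computed on the subject's planted latent coordinates — to a
    linear coefficient.
    """

    intercept: float = 0.0
    loadings: dict = field(default_factory=dict)
    noise_sd: float = 1.0


def default_clinical_specs() -> dict[str, ClinicalSpec]:
    """Clinical readouts mirroring the kinds of associations under study.

    Functioning loads (weakly) on attentional-network gradient means, a visual
    dysfunction score on attentional within-network dispersion, a cognition
    score on somatomotor dispersion, and a depression score is pure noise (a
    null column). Coefficients are intentionally modest so clinical
    correlations are weak, as in real early-stage cohorts.
    """
    return {
        "gaf": ClinicalSpec(60.0, {"nm_g1_DAN": 8.0, "nm_g1_VAN": 6.0}, 8.0),
        "visdys": ClinicalSpec(3.0, {"wd_DAN": -10.0}, 2.0),
        "cognition": ClinicalSpec(0.0, {"wd_SMN": 5.0}, 0.8),
        "bdi": ClinicalSpec(18.0, {}, 10.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort; fully determines it with ``seed``.

    Group sizes default to the study proportions (HC 376, ROP 243, ROD 212,
    CHR-P 240) scaled by ``scale`` and rounded; sites are balanced within group.
    """

    n_parcels: int = 100
    n_networks: int = 7
    scale: float = 0.1
    group_sizes: dict | None = None
    sites: tuple = ("site_A", "site_B")
    n_timepoints: int = 200
    amp: float = 1.0
    lengthscale: float = 0.5
    nugget: float = 0.05
    noise_sd: float = 0.05
    g1_scale: float = 1.0
    g2_scale: float = 0.8
    group_effects: dict = field(default_factory=dict)
    site_effects: dict = field(default_factory=dict)
    clinical: dict | None = None
    missing_rate: float = 0.1
    seed: int = 0

    def resolved_group_sizes(self) -> dict[str, int]:
        if self.group_sizes is not None:
            return dict(self.group_sizes)
        return {
            g: int(round(self.scale * n)) for g, n in FULL_GROUP_SIZES.items()
        }


def default_effect_config() -> dict[str, GroupEffect]:
    """Planted effects mirroring the reported direction of group differences.

    Somatomotor gradient-1 scores are raised in every patient group, ventral
    attention gradient-1 scores are lowered in the psychosis spectrum (ROP,
    CHR-P), and the depression group shows shrunk within-network dispersion in
    the attentional networks (DAN, VAN) plus a shrunk gradient-1 range.
    Magnitudes are free parameters of the generator chosen large enough to be
    recoverable at desk scale.
    """
    return {
        "ROP": GroupEffect(
            mean_shift={("SMN", 1): 0.06, ("VAN", 1): -0.06},
        ),
        "CHR-P": GroupEffect(
            mean_shift={("SMN", 1): 0.06, ("VAN", 1): -0.05},
        ),
        "ROD": GroupEffect(
            mean_shift={("SMN", 1): 0.06},
            dispersion_scale={"DAN": 0.55, "VAN": 0.40},
            range_scale=(0.95, 1.0),
        ),
    }


def default_site_effects(sites) -> dict[str, SiteEffect]:
    """Alternating mild scanner effects: amplitude scale and FC-edge offset."""
    out = {}
    for i, s in enumerate(sites):
        out[s] = SiteEffect(amp_scale=1.0 + 0.2 * (i % 2), fc_offset=0.05 * (i % 2))
    return out


@dataclass(frozen=True)
class CohortBundle:
    """A generated cohort: scheme, truth, per-subject series, covariate table."""

    scheme: ParcelScheme
    ground_truth: GroundTruth
    timeseries: dict  # subject_id -> (T, P) array
    cohort: pd.DataFrame
    subject_latent: dict  # subject_id -> (P, 2) array
    config: CohortConfig


def _planted_metrics(latent: np.ndarray, scheme: ParcelScheme) -> dict[str, float]:
    from .differentiation import metrics_table

    row = metrics_table({"s": latent}, scheme).iloc[0]
    return row.to_dict()


def synthesize_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full synthetic cohort from a config.

    Subjects are assigned to sites round-robin within group (balanced cells);
    a site x group cell with fewer than 2 subjects is a config error because the
    harmonization stage cannot estimate site effects from it.
    """
    sizes = config.resolved_group_sizes()
    if len(config.sites) < 2:
        raise ValueError("need >= 2 sites")
    if sum(n > 0 for n in sizes.values()) < 2:
        raise ValueError("need >= 2 non-empty groups")
    for g, n in sizes.items():
        if 0 < n < 2 * len(config.sites):
            raise ValueError(
                f"group {g!r} has {n} subjects over {len(config.sites)} sites: "
                "some site x group cell has < 2 subjects, too small to harmonize"
            )

    scheme = make_parcel_scheme(config.n_parcels, config.n_networks, seed=config.seed)
    site_effects = config.site_effects or default_site_effects(config.sites)
    gt = plant_ground_truth(
        scheme,
        group_effects=config.group_effects,
        site_effects=site_effects,
        noise_sd=config.noise_sd,
        g1_scale=config.g1_scale,
        g2_scale=config.g2_scale,
        seed=config.seed,
    )
    clinical_specs = (
        config.clinical if config.clinical is not None else default_clinical_specs()
    )

    root = np.random.SeedSequence(config.seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    rows = []
    timeseries = {}
    subject_latent = {}
    sid_counter = 0
    for grp in GROUPS:
        n = sizes.get(grp, 0)
        for i in range(n):
            sid = f"sub-{sid_counter:04d}"
            site = config.sites[i % len(config.sites)]
            age = float(np.clip(cov_rng.normal(27.5, 6.0), 18.0, 50.0))
            sex = int(cov_rng.random() < 0.55)
            mean_fd = float(max(cov_rng.normal(0.15, 0.05), 0.01))
            sub_ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(1, sid_counter)
            )
            jit_rng = np.random.default_rng(sub_ss)
            latent = gt.group_latent[grp] + gt.noise_sd * jit_rng.standard_normal(
                gt.base_latent.shape
            )
            ts_seed_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(2, sid_counter))
            )
            amp = config.amp * site_effects[site].amp_scale
            k = latent_covariance(latent, amp, config.lengthscale, config.nugget)
            chol = np.linalg.cholesky(k)
            z = ts_seed_rng.standard_normal((config.n_timepoints, config.n_parcels))
            timeseries[sid] = z @ chol.T
            subject_latent[sid] = latent

            clin_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(3, sid_counter))
            )
            planted = _planted_metrics(latent, scheme)
            clin = {}
            for name, spec in clinical_specs.items():
                val = spec.intercept + sum(
                    coef * planted[key] for key, coef in spec.loadings.items()
                )
                clin[name] = val + spec.noise_sd * clin_rng.standard_normal()
            rows.append(
                {"subject_id": sid, "group": grp, "site": site, "age": age,
                 "sex": sex, "mean_fd": mean_fd, **clin}
            )
            sid_counter += 1

    cohort = pd.DataFrame(rows)
    if config.missing_rate > 0 and clinical_specs:
        miss_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(4,))
        )
        for name in clinical_specs:
            holes = miss_rng.random(len(cohort)) < config.missing_rate
            cohort.loc[holes, name] = np.nan
    return CohortBundle(scheme, gt, timeseries, cohort, subject_latent, config)


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write a cohort to disk: scheme, cohort table (NA for missing), per-subject
    time-series TSVs, a manifest and a provenance record with all seeds."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    bundle.scheme.to_tsv(out / "parcel_scheme.tsv")
    bundle.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, na_rep="NA")
    manifest = {}
    for sid, ts in bundle.timeseries.items():
        path = out / "timeseries" / f"{sid}.tsv"
        np.savetxt(path, ts, delimiter="\t", fmt="%.8g")
        manifest[sid] = str(path.relative_to(out))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    cfg = asdict(bundle.config)
    cfg["group_effects"] = {
        g: {
            "mean_shift": {f"{n}:g{gi}": v for (n, gi), v in e.mean_shift.items()},
            "dispersion_scale": dict(e.dispersion_scale),
            "range_scale": list(e.range_scale),
        }
        for g, e in (bundle.config.group_effects or {}).items()
    }
    cfg["site_effects"] = {
        s: asdict(e) for s, e in bundle.ground_truth.site_effects.items()
    }
    cfg["clinical"] = {
        n: asdict(s) for n, s in (bundle.config.clinical or default_clinical_specs()).items()
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(cfg, fh, indent=1, default=str)
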