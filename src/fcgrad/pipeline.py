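"""Configuration-driven orchestration of the full gradient analysis.

Stages: synthesize (or load) cohort -> per-subject FC -> row thresholding ->
cosine affinity -> diffusion embedding -> HC-reference Procrustes alignment ->
ComBat site harmonization of gradient scores -> differentiation metrics (and
their harmonization) -> regional t-maps and rank-based network/metric
comparisons with FDR -> clinical screening and correlations -> receptor-map
spin-permutation association. Every intermediate table can be written to disk,
and a run log records config and seeds so any output is reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import combat, connectome, differentiation, gradients, spatial, stats
from .simulate import (
    CohortBundle,
    CohortConfig,
    GroupEffect,
    default_effect_config,
    synthesize_cohort,
)

DEFAULT_CONTRASTS = (
    ("HC", "ROP"),
    ("HC", "ROD"),
    ("HC", "CHR-P"),
    ("HC", ("ROP", "ROD", "CHR-P")),  # patients combined
)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run; serializes losslessly to/from YAML.

    Defaults follow the analysis conventions: 10% row density (20% as the
    sensitivity setting), 10 embedding components with anisotropy 0.5, 10 000
    spin permutations, alpha level .05, two-sided tests.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    density: float = 0.10
    sensitivity_densities: tuple = (0.10, 0.20)
    n_components: int = 10
    alpha: float = 0.5
    n_perm: int = 10_000
    alpha_level: float = 0.05
    seed: int = 0
    contrasts: tuple = DEFAULT_CONTRASTS
    preserve_group_in_combat: bool = True
    harmonize_metrics: bool = True
    spin_method: str = "nearest"
    n_receptor_systems: int = 3
    n_maps_per_receptor: int = 2

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one seed coherently to every stage."""
        return replace(self, seed=seed, cohort=replace(self.cohort, seed=seed))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["contrasts"] = [
            [a, list(b) if not isinstance(b, str) else b] for a, b in self.contrasts
        ]
        ge = {}
        for g, e in (self.cohort.group_effects or {}).items():
            ge[g] = {
                "mean_shift": {f"{n}:g{gi}": v for (n, gi), v in e.mean_shift.items()},
                "dispersion_scale": dict(e.dispersion_scale),
                "range_scale": list(e.range_scale),
            }
        d["cohort"]["group_effects"] = ge
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cdict = d.pop("cohort", {})
        ge = {}
        for g, e in (cdict.pop("group_effects", {}) or {}).items():
            ms = {}
            for key, v in e.get("mean_shift", {}).items():
                net, gi = key.split(":g")
                ms[(net, int(gi))] = v
            ge[g] = GroupEffect(
                mean_shift=ms,
                dispersion_scale=e.get("dispersion_scale", {}),
                range_scale=tuple(e.get("range_scale", (1.0, 1.0))),
            )
        for key in ("sites",):
            if key in cdict and cdict[key] is not None:
                cdict[key] = tuple(cdict[key])
        cohort = CohortConfig(**cdict, group_effects=ge)
        contrasts = tuple(
            (a, b if isinstance(b, str) else tuple(b))
            for a, b in d.pop("contrasts", [])
        )
        for key in ("sensitivity_densities",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, contrasts=contrasts or DEFAULT_CONTRASTS, **d)


def smoke_config(seed: int = 0, effects: bool = True, n_perm: int = 500) -> PipelineConfig:
    """Desk-scale configuration: ~107 subjects, 100 parcels, reduced spins."""
    cohort = CohortConfig(
        n_parcels=100,
        scale=0.1,
        group_effects=default_effect_config() if effects else {},
        seed=seed,
    )
    return PipelineConfig(cohort=cohort, n_perm=n_perm, seed=seed)


@dataclass
class PipelineResult:
    """Results bundle; every table is also written to out_dir when given."""

    bundle: CohortBundle
    fc: dict
    gradient_sets: dict  # subject_id -> aligned GradientSet
    reference: gradients.ReferenceGradient
    scores_g1: pd.DataFrame  # harmonized subjects x parcels
    scores_g2: pd.DataFrame
    metrics: pd.DataFrame  # harmonized differentiation metrics
    ev_table: pd.DataFrame
    ev_anova: dict
    tmaps: dict  # (gradient, contrast_label) -> regional glm table
    network_tests: pd.DataFrame
    clinical_correlations: pd.DataFrame
    receptor_table: pd.DataFrame
    log: dict


def _contrast_label(contrast) -> str:
    ref, other = contrast
    return f"{ref} vs {other if isinstance(other, str) else 'PAT'}"


def subject_fc_matrices(bundle: CohortBundle) -> dict[str, np.ndarray]:
    """Fisher-z FC per subject, with the site-level additive edge offset applied."""
    fcs = {}
    site_eff = bundle.ground_truth.site_effects
    site_of = dict(zip(bundle.cohort["subject_id"], bundle.cohort["site"]))
    for sid, ts in bundle.timeseries.items():
        fc = connectome.compute_fc(ts)
        eff = site_eff.get(site_of[sid])
        if eff is not None and eff.fc_offset:
            fc = fc + eff.fc_offset
            np.fill_diagonal(fc, 0.0)
        fcs[sid] = fc
    return fcs


def embed_subjects(
    fcs: dict[str, np.ndarray],
    hc_ids: list[str],
    density: float,
    n_components: int,
    alpha: float,
) -> tuple[dict[str, gradients.GradientSet], gradients.ReferenceGradient]:
    """Embed every subject and align to the HC-mean reference."""
    reference = gradients.build_reference(
        [fcs[s] for s in hc_ids], density, n_components, alpha
    )
    aligned = {}
    for sid, fc in fcs.items():
        g = gradients.diffusion_embed(
            connectome.cosine_affinity(connectome.threshold_rows(fc, density)),
            n_components,
            alpha,
        )
        aligned[sid] = gradients.procrustes_align(g, reference)
    return aligned, reference


def synthetic_receptor_maps(
    scheme, n_systems: int, n_maps: int, seed: int
) -> tuple[dict[str, list[np.ndarray]], dict[str, str]]:
    """Smooth synthetic stand-ins for PET receptor-density maps.

    Each map is a random low-order function of the parcel centroids (a random
    linear combination of the coordinates plus their pairwise products), so maps
    are spatially autocorrelated the way real receptor maps are. Maps of the
    same receptor type share structure plus independent noise. These are
    synthetic stand-ins: no published PET data enters the pipeline.
    """
    rng = np.random.default_rng(seed)
    cent = scheme.centroids
    basis = np.column_stack(
        [cent, cent[:, [0]] * cent[:, [1]], cent[:, [1]] * cent[:, [2]],
         cent[:, [0]] * cent[:, [2]], cent**2]
    )
    maps: dict[str, list[np.ndarray]] = {}
    systems: dict[str, str] = {}
    for s in range(n_systems):
        rtype = f"receptor_{s + 1}"
        systems[rtype] = f"system_{s + 1}"
        shared = basis @ rng.standard_normal(basis.shape[1])
        shared = (shared - shared.mean()) / shared.std()
        maps[rtype] = [
            shared + 0.3 * rng.standard_normal(len(cent)) for _ in range(n_maps)
        ]
    return maps, systems


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute every stage on a (synthetic) cohort; see module docstring."""
    t_start = time.time()
    log: dict = {"config_seed": config.seed, "stages": {}}

    def _stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log["stages"][name] = round(time.time() - t0, 3)
        return result

    bundle = _stage("simulate", lambda: synthesize_cohort(config.cohort))
    cohort = bundle.cohort
    hc_ids = cohort.loc[cohort["group"] == "HC", "subject_id"].tolist()

    fcs = _stage("fc", lambda: subject_fc_matrices(bundle))
    aligned, reference = _stage(
        "embed+align",
        lambda: embed_subjects(
            fcs, hc_ids, config.density, config.n_components, config.alpha
        ),
    )

    sids = cohort["subject_id"].tolist()
    covars = cohort[["age", "sex", "mean_fd"]].to_numpy(dtype=float)
    design_cols = [covars]
    if config.preserve_group_in_combat:
        design_cols.insert(
            0, pd.get_dummies(cohort["group"], drop_first=True).to_numpy(dtype=float)
        )
    design = pd.DataFrame(np.column_stack(design_cols), index=cohort.index)

    def _harmonize_scores(component: int) -> pd.DataFrame:
        raw = pd.DataFrame(
            np.stack([aligned[s].scores[:, component] for s in sids]),
            index=sids,
            columns=[f"p{i}" for i in range(bundle.scheme.n_parcels)],
        )
        return combat.combat_adjust(raw, cohort["site"], design).adjusted

    scores_g1 = _stage("combat_g1", lambda: _harmonize_scores(0))
    scores_g2 = _stage("combat_g2", lambda: _harmonize_scores(1))

    def _metrics() -> pd.DataFrame:
        per_subject = {
            s: np.column_stack([scores_g1.loc[s], scores_g2.loc[s]]) for s in sids
        }
        m = differentiation.metrics_table(per_subject, bundle.scheme)
        if config.harmonize_metrics:
            m = combat.combat_adjust(m, cohort["site"], design).adjusted
        return m

    metrics = _stage("metrics", _metrics)

    ev_table = _stage(
        "explained_variance",
        lambda: gradients.explained_variance_table({s: aligned[s] for s in sids}),
    )
    ev_anova = {}
    for g in ("ev_g1", "ev_g2"):
        res, dfs = stats.explained_variance_anova(
            ev_table[g].to_numpy(), cohort["group"]
        )
        ev_anova[g] = {"F": res.estimate, "p": res.p, "df": dfs}

    covar_df = cohort[["age", "sex", "mean_fd"]]
    tmaps = {}
    for contrast in config.contrasts:
        label = _contrast_label(contrast)
        for gname, table in (("g1", scores_g1), ("g2", scores_g2)):
            tmaps[(gname, label)] = stats.regional_glm(
                table.to_numpy(), cohort["group"], contrast, covar_df
            )
    log["stages"]["regional_glm"] = True

    network_tests = _stage(
        "network_tests",
        lambda: stats.network_comparisons(
            metrics, cohort.set_index("subject_id").loc[sids].reset_index(),
            list(config.contrasts),
        ),
    )

    def _clinical() -> pd.DataFrame:
        clin_cols = [
            c for c in cohort.columns
            if c not in ("subject_id", "group", "site", "age", "sex", "mean_fd")
        ]
        if not clin_cols:
            return pd.DataFrame()
        screened, report = stats.screen_and_impute_clinical(cohort, clin_cols)
        log["clinical_screen"] = report
        keep = metrics.loc[screened["subject_id"]]
        return stats.clinical_correlations(keep, screened[clin_cols])

    clin_corr = _stage("clinical", _clinical)

    def _receptors() -> pd.DataFrame:
        raw_maps, systems = synthetic_receptor_maps(
            bundle.scheme, config.n_receptor_systems, config.n_maps_per_receptor,
            seed=config.seed + 101,
        )
        averaged = spatial.average_receptor_maps(raw_maps)
        spins = spatial.spin_permutation_indices(
            bundle.scheme, config.n_perm, seed=config.seed + 202,
            method=config.spin_method,
        )
        tmap_arrays = {
            f"{g}:{lab}": t["t"].to_numpy() for (g, lab), t in tmaps.items()
        }
        return spatial.receptor_association(tmap_arrays, averaged, spins, systems)

    receptor_table = _stage("receptor_association", _receptors)

    log["total_seconds"] = round(time.time() - t_start, 3)
    result = PipelineResult(
        bundle=bundle, fc=fcs, gradient_sets=aligned, reference=reference,
        scores_g1=scores_g1, scores_g2=scores_g2, metrics=metrics,
        ev_table=ev_table, ev_anova=ev_anova, tmaps=tmaps,
        network_tests=network_tests, clinical_correlations=clin_corr,
        receptor_table=receptor_table, log=log,
    )
    if out_dir is not None:
        write_results(result, config, out_dir)
    return result


def write_results(result: PipelineResult, config: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    result.bundle.scheme.to_tsv(out / "parcel_scheme.tsv")
    result.bundle.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, na_rep="NA")
    result.scores_g1.to_csv(out / "scores_g1_harmonized.tsv", sep="\t")
    result.scores_g2.to_csv(out / "scores_g2_harmonized.tsv", sep="\t")
    result.metrics.to_csv(out / "metrics.tsv", sep="\t")
    result.ev_table.to_csv(out / "explained_variance.tsv", sep="\t", index=False)
    result.network_tests.to_csv(out / "network_tests.tsv", sep="\t", index=False)
    if len(result.clinical_correlations):
        result.clinical_correlations.to_csv(
            out / "clinical_correlations.tsv", sep="\t", index=False
        )
    result.receptor_table.to_csv(out / "receptor_association.tsv", sep="\t", index=False)
    tmap_rows = []
    for (g, lab), t in result.tmaps.items():
        tt = t.copy()
        tt.insert(0, "gradient", g)
        tt.insert(1, "contrast", lab)
        tmap_rows.append(tt)
    pd.concat(tmap_rows).to_csv(out / "tmaps.tsv", sep="\t", index=False)
    summary = {
        "n_subjects": len(result.bundle.cohort),
        "n_parcels": result.bundle.scheme.n_parcels,
        "ev_anova": result.ev_anova,
        "n_significant_network_tests": int(
            (result.network_tests["q"] < config.alpha_level).sum()
        ),
        "log": result.log,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)


def density_sensitivity(
    config: PipelineConfig, densities: tuple | None = None
) -> pd.DataFrame:
    """Gradient correspondence of the HC reference across threshold densities.

    Re-embeds the healthy-control mean FC at each density and matches gradients
    of each non-baseline density to the baseline (first) density by maximal
    absolute correlation, solved as a one-to-one assignment — row thresholding
    density can switch gradient order, which the matching absorbs. Returns a
    tidy table: density, baseline gradient, matched gradient, |r|.
    """
    densities = tuple(densities or config.sensitivity_densities)
    if len(densities) < 2:
        raise ValueError("need >= 2 densities")
    bundle = synthesize_cohort(config.cohort)
    cohort = bundle.cohort
    hc_ids = cohort.loc[cohort["group"] == "HC", "subject_id"].tolist()
    fcs = subject_fc_matrices(bundle)
    refs = {
        d: gradients.build_reference(
            [fcs[s] for s in hc_ids], d, config.n_components, config.alpha
        ).scores
        for d in densities
    }
    base_d = densities[0]
    base = refs[base_d]
    rows = []
    for d in densities[1:]:
        other = refs[d]
        k = base.shape[1]
        corr = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                corr[i, j] = abs(np.corrcoef(base[:, i], other[:, j])[0, 1])
        ri, cj = linear_sum_assignment(-corr)
        for i, j in zip(ri, cj):
            rows.append({
                "density": d, "baseline_density": base_d,
                "baseline_gradient": i + 1, "matched_gradient": j + 1,
                "abs_r": corr[i, j],
            })
    return pd.DataFrame(rows)
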