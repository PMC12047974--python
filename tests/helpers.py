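"""Shared independent oracles and simulators used across test modules."""

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def brute_force_dispersion(g1, g2, scheme):
    """Independent double-loop implementation of the dispersion metrics."""
    pts = {i: (g1[i], g2[i]) for i in range(len(g1))}
    cent, within = {}, {}
    for net in scheme.networks:
        idx = scheme.network_indices(net)
        xs = sorted(pts[i][0] for i in idx)
        ys = sorted(pts[i][1] for i in idx)

        def med(v):
            m = len(v) // 2
            return v[m] if len(v) % 2 else 0.5 * (v[m - 1] + v[m])

        cx, cy = med(xs), med(ys)
        cent[net] = (cx, cy)
        total = 0.0
        for i in idx:
            total += ((pts[i][0] - cx) ** 2 + (pts[i][1] - cy) ** 2) ** 0.5
        within[net] = total / len(idx)
    between = {}
    for a, b in combinations(scheme.networks, 2):
        (ax, ay), (bx, by) = cent[a], cent[b]
        between[f"{a}|{b}"] = ((ax - bx) ** 2 + (ay - by) ** 2) ** 0.5
    return cent, within, between


def smooth_map_factory(scheme, lengthscale=0.5, nugget=0.1):
    """Sampler of spatially autocorrelated maps (GP over the sphere)."""
    c = scheme.centroids
    k = np.exp(-cdist(c, c) ** 2 / (2 * lengthscale**2)) + nugget * np.eye(len(c))
    chol = np.linalg.cholesky(k)

    def draw(rng):
        return chol @ rng.standard_normal(len(c))

    return draw


def simulated_site_features(seed=3, n_per_site=100, n_feat=20, site_offset=2.0,
                            group_effect=0.0):
    """Two sites, balanced groups, additive site offset 2.0 on every feature.

    Feature noise scales vary in [0.2, 0.5] — homogeneous unit-variance
    features make the site parameters fully exchangeable across features, an
    edge case where empirical-Bayes shrinkage leaves a sampling-noise residual
    that no reference implementation avoids either.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_site
    site = np.repeat(["s1", "s2"], n_per_site)
    group = np.tile(np.repeat(["HC", "PAT"], n_per_site // 2), 2)
    scales = rng.uniform(0.2, 0.5, n_feat)
    x = rng.standard_normal((n, n_feat)) * scales
    x += np.where(site == "s2", site_offset, 0.0)[:, None]
    x += np.where(group == "PAT", group_effect, 0.0)[:, None]
    features = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_feat)])
    design = pd.DataFrame({"pat": (group == "PAT").astype(float)})
    return features, pd.Series(site), design, group
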