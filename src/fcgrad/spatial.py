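"""Spatially constrained null models and receptor-map association.

Parcel-level brain maps are spatially autocorrelated, so naive permutation tests
of map-map correlations are anticonservative. The spin test rotates one map over
the spherical geometry of the parcel centroids — preserving its spatial
autocorrelation while destroying its alignment with the other map — and compares
the observed correlation against the rotated null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scheme import ParcelScheme
from .stats import fdr_bh


@dataclass(frozen=True)
class SpinNull:
    """Precomputed spin permutations: each row reassigns parcel values.

    ``permutations[r, i] = j`` means that in rotation r, parcel i takes the value
    of source parcel j (always within the same hemisphere).
    """

    permutations: np.ndarray  # (n_perm, P) int
    seed: int
    method: str

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]

    def apply(self, values: np.ndarray) -> np.ndarray:
        """(n_perm, P) array of spun copies of ``values``."""
        return np.asarray(values, dtype=float)[self.permutations]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random 3-D rotation via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _one_to_one(dist: np.ndarray) -> np.ndarray:
    """Greedy one-to-one assignment: repeatedly match the globally closest pair."""
    d = dist.copy()
    n = d.shape[0]
    perm = np.full(n, -1, dtype=int)
    for _ in range(n):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        perm[i] = j
        d[i, :] = np.inf
        d[:, j] = np.inf
    return perm


def spin_permutation_indices(
    scheme: ParcelScheme,
    n_perm: int,
    seed: int = 0,
    method: str = "nearest",
    include_identity: bool = False,
) -> SpinNull:
    """Build spin permutations over a scheme's spherical centroids.

    For each permutation a uniform random rotation is applied to the left
    hemisphere and its x-mirrored counterpart to the right hemisphere (so both
    hemispheres spin coherently); each parcel is then reassigned the value of the
    source parcel whose rotated centroid lands nearest, within its hemisphere.

    Parameters
    ----------
    method:
        "nearest" (default): nearest-neighbour reassignment, duplicates allowed.
        "one-to-one": greedy one-to-one matching — every source used exactly
        once, so each spun map is an exact permutation of the original values.
    include_identity:
        Make row 0 the identity permutation (a test hook).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("nearest", "one-to-one"):
        raise ValueError(f"unknown spin method {method!r}")
    cent = scheme.centroids
    norms = np.linalg.norm(cent, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("centroids must lie on the unit sphere")
    hemi = scheme.hemispheres
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    p = scheme.n_parcels
    perms = np.empty((n_perm, p), dtype=int)
    hemi_idx = {h: np.flatnonzero(hemi == h) for h in ("L", "R")}
    for r in range(n_perm):
        if include_identity and r == 0:
            perms[r] = np.arange(p)
            continue
        rot_l = _random_rotation(rng)
        rot_r = mirror @ rot_l @ mirror
        for h, rot in (("L", rot_l), ("R", rot_r)):
            idx = hemi_idx[h]
            if idx.size == 0:
                continue
            pts = cent[idx]
            rotated = pts @ rot.T
            dist = cdist(pts, rotated)
            if method == "nearest":
                assign = np.argmin(dist, axis=1)
            else:
                assign = _one_to_one(dist)
            perms[r, idx] = idx[assign]
    return SpinNull(permutations=perms, seed=seed, method=method)


def spatial_correlation_test(
    map_a: np.ndarray, map_b: np.ndarray, spins: SpinNull
) -> dict:
    """Pearson correlation of two parcel maps with a spin-permutation p-value.

    ``map_a`` is the map that gets spun. Two-sided
    p_spin = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm), so the smallest
    attainable p is 1 / (n_perm + 1).
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("maps must have equal length")
    if a.size != spins.permutations.shape[1]:
        raise ValueError("spins were built on a different parcel count")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant map: correlation undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    spun = spins.apply(a)  # (n_perm, P)
    spun_c = spun - spun.mean(axis=1, keepdims=True)
    b_c = b - b.mean()
    denom = np.linalg.norm(spun_c, axis=1) * np.linalg.norm(b_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (spun_c @ b_c) / denom
    r_null = r_null[np.isfinite(r_null)]
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1.0 + spins.n_perm)
    return {"r": r_obs, "p_spin": float(p), "n_perm": spins.n_perm}


def average_receptor_maps(
    maps: dict[str, list[np.ndarray]]
) -> dict[str, np.ndarray]:
    """Average same-receptor maps after z-scoring each across parcels.

    Input maps for one receptor type may come from different tracers/cohorts on
    different scales; z-scoring puts them on a common scale before the mean.
    Singleton groups pass through z-scored.
    """
    lengths = {len(m) for group in maps.values() for m in group}
    if len(lengths) > 1:
        raise ValueError(f"mismatched map lengths: {sorted(lengths)}")
    out = {}
    for rtype, group in maps.items():
        z = []
        for m in group:
            m = np.asarray(m, dtype=float)
            sd = m.std()
            if sd == 0:
                raise ValueError(f"constant receptor map in group {rtype!r}")
            z.append((m - m.mean()) / sd)
        out[rtype] = np.mean(z, axis=0)
    return out


def receptor_association(
    tmaps: dict[str, np.ndarray],
    receptor_maps: dict[str, np.ndarray],
    spins: SpinNull,
    systems: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Correlate every t-map with every receptor map under the spin null.

    Returns a tidy table (one row per t-map x receptor) with Pearson r, spin p
    and BH-FDR q across the whole table (one correction family per call).
    """
    if not tmaps or not receptor_maps:
        raise ValueError("empty t-map or receptor-map input")
    rows = []
    for tname, tmap in tmaps.items():
        for rname, rmap in receptor_maps.items():
            res = spatial_correlation_test(tmap, rmap, spins)
            rows.append({
                "tmap": tname,
                "receptor": rname,
                "system": (systems or {}).get(rname, ""),
                "r": res["r"],
                "p_spin": res["p_spin"],
            })
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p_spin"].to_numpy())
    return out
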