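"""Parcellation schemes: parcel ids, network labels, hemispheres and spherical centroids.

A parcel scheme is the coordinate frame shared by every stage of the pipeline:
connectivity matrices, gradient maps, dispersion metrics and spin permutations all
index parcels through it. Synthetic schemes mimic the structure of the Schaefer
parcellation annotated with the seven Yeo networks: parcels split between the two
hemispheres, each network spatially contiguous on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical seven-network labels (Yeo ordering): visual, somatomotor, dorsal
#: attention, ventral attention / salience, limbic, frontoparietal control,
#: default mode.
YEO7_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ParcelScheme:
    """A parcel table: id, network label, hemisphere and unit-sphere centroid.

    Parameters
    ----------
    table:
        DataFrame with columns ``parcel_id`` (0-based, consecutive), ``network``
        (categorical label), ``hemisphere`` ({"L", "R"}) and ``cx, cy, cz``
        (centroid on the unit sphere).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["parcel_id", "network", "hemisphere", "cx", "cy", "cz"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"scheme table missing columns: {missing}")
        pid = t["parcel_id"].to_numpy()
        if not np.array_equal(pid, np.arange(len(t))):
            raise ValueError("parcel_ids must be consecutive 0-based integers")
        norms = np.linalg.norm(t[["cx", "cy", "cz"]].to_numpy(), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere")
        if len(t) >= 2 and set(t["hemisphere"]) != {"L", "R"}:
            raise ValueError("both hemispheres must be non-empty")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Network labels in first-appearance order."""
        return list(dict.fromkeys(self.table["network"]))

    @property
    def centroids(self) -> np.ndarray:
        """(P, 3) array of unit-sphere centroids."""
        return self.table[["cx", "cy", "cz"]].to_numpy(dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def network_indices(self, network: str) -> np.ndarray:
        """Parcel indices belonging to ``network``."""
        idx = np.flatnonzero((self.table["network"] == network).to_numpy())
        if idx.size == 0:
            raise ValueError(f"unknown or empty network: {network!r}")
        return idx

    def network_indicator(self) -> pd.DataFrame:
        """Parcel-by-network 0/1 membership matrix."""
        return pd.get_dummies(self.table["network"]).astype(int)[self.networks]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelScheme":
        return cls(pd.read_csv(path, sep="\t"))


def _hemisphere_points(n: int, phase: float) -> np.ndarray:
    """Quasi-uniform points on the left (x <= 0) unit hemisphere.

    A Fibonacci lattice over the full sphere folded onto x <= 0; deterministic
    given n and the golden-angle phase offset.
    """
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE + phase
    x = -np.abs(r * np.cos(phi))
    y = r * np.sin(phi)
    pts = np.column_stack([x, y, z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_parcel_scheme(
    n_parcels: int, n_networks: int = 7, seed: int = 0
) -> ParcelScheme:
    """Build a synthetic parcel scheme with spatially contiguous networks.

    Centroids are placed on the unit sphere by a deterministic quasi-uniform
    (Fibonacci) lattice on the left hemisphere; the right hemisphere mirrors the
    left in the x coordinate. Within each hemisphere, networks are contiguous
    bands of centroids ordered by z, so network labels are spatially coherent —
    a prerequisite for spin-permutation nulls to be meaningful.

    Parameters
    ----------
    n_parcels:
        Total parcel count; must be at least ``2 * n_networks`` so every network
        has a parcel in each hemisphere.
    n_networks:
        Number of networks; 7 uses the Yeo labels, other counts use N1..Nk.
    seed:
        Rotates the golden-angle phase of the lattice; the construction is fully
        deterministic given (n_parcels, n_networks, seed).
    """
    if n_networks < 2:
        raise ValueError(f"n_networks must be >= 2, got {n_networks}")
    if n_parcels < 2 * n_networks:
        raise ValueError(
            f"n_parcels must be >= 2 * n_networks ({2 * n_networks}), got {n_parcels}"
        )
    if n_networks == 7:
        names = list(YEO7_NETWORKS)
    else:
        names = [f"N{i + 1}" for i in range(n_networks)]

    n_left = (n_parcels + 1) // 2
    n_right = n_parcels - n_left
    phase = 0.1 * (seed % 1000)
    left = _hemisphere_points(n_left, phase)
    right = _hemisphere_points(n_right, phase) * np.array([-1.0, 1.0, 1.0])

    rows = []
    for hemi, pts in (("L", left), ("R", right)):
        order = np.argsort(-pts[:, 2], kind="stable")
        blocks = np.array_split(order, n_networks)
        for name, block in zip(names, blocks):
            for j in block:
                rows.append((name, hemi, *pts[j]))
    table = pd.DataFrame(rows, columns=["network", "hemisphere", "cx", "cy", "cz"])
    table.insert(0, "parcel_id", np.arange(len(table)))
    return ParcelScheme(table)
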