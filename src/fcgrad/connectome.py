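"""Functional connectivity: Pearson/Fisher-z FC matrices, row-density thresholding,
and the cosine-similarity affinity matrix that feeds the gradient embedding."""

from __future__ import annotations

import numpy as np

# r values numerically at +/-1 are clipped before atanh so Fisher z stays finite
_R_CLIP = 1.0 - 1e-7


def compute_fc(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z functional connectivity of a timepoints-by-parcels matrix.

    Off-diagonal entries are atanh(Pearson r) between parcel time series, with r
    clipped to +/-(1 - 1e-7) before the transform; the diagonal is set to 0.

    Raises
    ------
    ValueError
        If any parcel has zero temporal variance (signal dropout), naming the
        offending parcel ids.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be a (timepoints, parcels) matrix with >= 2 rows")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series for parcel_id(s) {dead.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def threshold_rows(fc: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep, per row, the k = floor(density * (P - 1)) largest off-diagonal entries.

    Selection is by signed value (strongest = most positive), the diagonal is
    excluded, and everything else in the row is set to 0. Ties at the k-th value
    keep the lowest parcel_id. The result is generally asymmetric and is not
    symmetrized: downstream cosine similarity compares connectivity *profiles*
    (rows), for which symmetry is irrelevant.
    """
    fc = np.asarray(fc, dtype=float)
    p = fc.shape[0]
    if fc.shape != (p, p):
        raise ValueError("fc must be square")
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0, 1), got {density}")
    k = int(np.floor(density * (p - 1)))
    if k == 0:
        raise ValueError(
            f"density {density} keeps 0 connections per row at P={p}; increase density"
        )
    work = fc.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort on the negated row -> among ties, lowest parcel_id first
    order = np.argsort(-work, axis=1, kind="stable")
    keep = order[:, :k]
    out = np.zeros_like(fc)
    rows = np.repeat(np.arange(p), k)
    out[rows, keep.ravel()] = fc[rows, keep.ravel()]
    return out


def cosine_affinity(thresholded: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Cosine similarity between thresholded connectivity rows.

    Entry (i, j) is dot(row_i, row_j) / (||row_i|| ||row_j||). Negative
    similarities are passed through by default; ``clamp=True`` floors them at 0.

    Raises
    ------
    ValueError
        If some row is entirely zero (no surviving connections), naming it.
    """
    x = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValueError(f"all-zero thresholded row for parcel_id(s) {dead.tolist()}")
    a = (x @ x.T) / np.outer(norms, norms)
    a = (a + a.T) / 2.0
    np.clip(a, -1.0, 1.0, out=a)
    if clamp:
        np.clip(a, 0.0, 1.0, out=a)
    return a


def write_matrix_tsv(path, matrix: np.ndarray, **meta) -> None:
    """Write a square matrix as TSV with a one-line ``# key=value`` comment header."""
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items()) if meta else "#"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, matrix, delimiter="\t", fmt="%.10g")


def read_matrix_tsv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", comments="#")
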