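"""Diffusion-map gradients of functional connectivity.

The embedding treats the cosine affinity matrix as a weighted graph, applies
anisotropic degree normalization (alpha), row-normalizes to a Markov transition
matrix and takes its leading non-trivial eigenvectors. Each eigenvector is one
"gradient": an axis along which connectivity profiles vary smoothly. Subject
gradients are aligned to a reference (derived from the healthy-control mean FC)
by orthogonal Procrustes rotation, which resolves sign flips, component swaps and
rotations without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .connectome import cosine_affinity, threshold_rows
from .scheme import ParcelScheme


@dataclass(frozen=True)
class GradientSet:
    """Per-subject gradient scores with spectral bookkeeping.

    Attributes
    ----------
    scores:
        (parcels, n_components) matrix; column c is gradient c+1.
    eigenvalues:
        Markov-matrix eigenvalues of the retained components, non-increasing.
    explained_variance:
        eigenvalue / sum(retained eigenvalues); entries in [0, 1], summing to 1.
    aligned:
        Whether the scores have been Procrustes-aligned to a reference.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    aligned: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("gradient scores must be finite")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class ReferenceGradient:
    """Group-level reference gradients used as the Procrustes target."""

    gradients: GradientSet
    provenance: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return self.gradients.scores


def _fix_column_signs(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|.| entry of each column is positive."""
    out = scores.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, c] = -col
    return out


def diffusion_embed(
    affinity: np.ndarray, n_components: int = 10, alpha: float = 0.5
) -> GradientSet:
    """Diffusion-map embedding of a symmetric affinity matrix.

    Construction: shift the affinity to be non-negative if it has a negative
    minimum (shift recorded in provenance); form W' = D^-alpha W D^-alpha; row
    normalize to a Markov matrix; eigendecompose; drop the trivial constant
    eigenvector; return the next ``n_components`` eigenvectors scaled by the
    automatic-diffusion-time factor lambda / (1 - lambda). Column signs follow a
    deterministic convention (largest-magnitude entry positive).

    alpha in [0, 1] controls how strongly sampling density is normalized out;
    0.5 is the usual anisotropic default.

    Raises
    ------
    ValueError
        If the affinity graph is disconnected (reducible Markov chain) — the
        usual symptom of over-aggressive thresholding upstream.
    """
    w = np.asarray(affinity, dtype=float)
    p = w.shape[0]
    if w.shape != (p, p) or not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("affinity must be square and symmetric")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 1 <= n_components < p:
        raise ValueError(f"n_components must be in [1, {p - 1}], got {n_components}")

    shift = 0.0
    wmin = w.min()
    if wmin < 0:
        shift = -wmin
        w = w + shift
    w = (w + w.T) / 2.0

    n_comp_graph, _ = connected_components((w > 0).astype(np.int8), directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp_graph} components); "
            "the Markov chain is reducible — lower the threshold density"
        )

    d = w.sum(axis=1)
    if alpha > 0:
        w = w / np.outer(d**alpha, d**alpha)
    d1 = w.sum(axis=1)
    # symmetric conjugate of the Markov matrix: shares its eigenvalues, eigh is stable
    inv_sqrt = 1.0 / np.sqrt(d1)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1][: n_components + 1]
    lam = evals[order]
    psi = evecs[:, order] * inv_sqrt[:, None]
    # normalize against the trivial constant eigenvector
    psi = psi / psi[:, [0]]
    lam_rest = lam[1:]
    scale = lam_rest / (1.0 - lam_rest)
    scores = _fix_column_signs(psi[:, 1:] * scale)
    ev = lam_rest / lam_rest.sum()
    return GradientSet(
        scores=scores,
        eigenvalues=lam_rest,
        explained_variance=ev,
        aligned=False,
        provenance={"alpha": alpha, "affinity_shift": shift, "diffusion_time": "auto"},
    )


def build_reference(
    hc_fc_matrices: list[np.ndarray],
    density: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
) -> ReferenceGradient:
    """Reference gradients from the element-wise mean of healthy-control Fisher-z FC.

    The mean FC matrix goes through the same threshold -> cosine affinity ->
    diffusion embedding path as any subject.
    """
    if not hc_fc_matrices:
        raise ValueError("need at least one control FC matrix")
    shapes = {m.shape for m in hc_fc_matrices}
    if len(shapes) != 1:
        raise ValueError(f"parcel-count mismatch across control FC matrices: {shapes}")
    mean_fc = np.mean(np.stack(hc_fc_matrices), axis=0)
    grads = diffusion_embed(
        cosine_affinity(threshold_rows(mean_fc, density)), n_components, alpha
    )
    return ReferenceGradient(
        gradients=grads,
        provenance={
            "n_controls": len(hc_fc_matrices),
            "density": density,
            "n_components": n_components,
            "alpha": alpha,
        },
    )


def procrustes_align(subject: GradientSet, reference: ReferenceGradient) -> GradientSet:
    """Orthogonal Procrustes alignment of subject gradients to the reference.

    Finds the orthogonal matrix R minimizing ||S R - Ref||_F (no scaling, no
    extra centering) and returns S R. Eigenvalues and explained variance are
    untouched: rotation mixes axes but the spectrum belongs to the subject's own
    embedding.
    """
    ref = reference.scores
    s = subject.scores
    if s.shape != ref.shape:
        raise ValueError(f"shape mismatch: subject {s.shape} vs reference {ref.shape}")
    if subject.aligned:
        raise ValueError("subject gradients are already aligned")
    r, _ = scipy.linalg.orthogonal_procrustes(s, ref)
    sv = scipy.linalg.svdvals(s.T @ ref)
    if sv[-1] < 1e-12 * max(sv[0], 1.0):
        raise ValueError(
            "degenerate (rank-deficient) cross-product between subject and "
            "reference; request more embedding components"
        )
    return replace(subject, scores=s @ r, aligned=True)


def explained_variance_table(
    gradient_sets: dict[str, GradientSet] | list[GradientSet],
) -> pd.DataFrame:
    """Tidy per-subject explained-variance ratios for gradients 1 and 2."""
    if isinstance(gradient_sets, list):
        gradient_sets = {str(i): g for i, g in enumerate(gradient_sets)}
    counts = {g.n_components for g in gradient_sets.values()}
    if len(counts) > 1:
        raise ValueError(f"mixed component counts: {sorted(counts)}")
    rows = [
        {"subject_id": sid, "ev_g1": g.explained_variance[0], "ev_g2": g.explained_variance[1]}
        for sid, g in gradient_sets.items()
    ]
    return pd.DataFrame(rows)


def label_gradients(scores: np.ndarray, scheme: ParcelScheme) -> dict[int, str]:
    """Convenience labels for the first two gradients.

    Each gradient is correlated with two network-indicator contrasts: VN minus
    SMN (the visual-to-sensorimotor axis) and sensory (VN+SMN) minus association
    (FPN+DMN) (the sensory-to-association axis); the better-matching contrast
    names the gradient. Labels are descriptive output only — ordering is always
    as computed, since gradient order is known to switch between datasets.
    """
    ind = scheme.network_indicator()
    have = set(scheme.networks)
    if not {"VN", "SMN", "FPN", "DMN"} <= have:
        return {c: f"gradient-{c + 1}" for c in range(min(2, scores.shape[1]))}
    contrasts = {
        "visual-to-sensorimotor": ind["VN"].to_numpy() - ind["SMN"].to_numpy(),
        "sensory-to-association": (ind["VN"].to_numpy() + ind["SMN"].to_numpy())
        - (ind["FPN"].to_numpy() + ind["DMN"].to_numpy()),
    }
    names = list(contrasts)
    k = min(2, scores.shape[1])
    corr = np.zeros((k, len(names)))
    for c in range(k):
        for j, name in enumerate(names):
            corr[c, j] = abs(np.corrcoef(scores[:, c], contrasts[name])[0, 1])
    # one-to-one assignment so the two gradients get distinct labels
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-corr)
    return {int(c): names[j] for c, j in zip(rows, cols)}


def write_gradients_tsv(path, gradients: GradientSet) -> None:
    k = gradients.n_components
    df = pd.DataFrame(gradients.scores, columns=[f"g{i + 1}" for i in range(k)])
    df.insert(0, "parcel_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
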