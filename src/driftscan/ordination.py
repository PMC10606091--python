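"""Classical (Torgerson) metric MDS of a population distance matrix.

Double-center the squared distances, eigendecompose, and scale the leading
eigenvectors by the square roots of their eigenvalues. The method is
closed-form and deterministic, recovers a Euclidean configuration exactly
when one exists, and degrades gracefully (zeroed axes with a warning) when
the input is not Euclidean-realizable, as coancestry distances need not be.

Axis-sign convention: within each retained axis the loading of largest
magnitude is made positive; ties on magnitude are resolved toward the
highest population index. This makes runs bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gendist import DistanceMatrix
from .genio import InputError

log = logging.getLogger(__name__)

__all__ = ["MDSResult", "classical_mds", "embedding_distortion"]


@dataclass
class MDSResult:
    labels: list[str]
    coords: np.ndarray  # (n populations, k dimensions)
    eigenvalues: np.ndarray  # the k retained eigenvalues, descending
    all_eigenvalues: np.ndarray  # full spectrum, descending


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    out = coords.copy()
    for j in range(out.shape[1]):
        v = out[:, j]
        mags = np.abs(v)
        mmax = mags.max()
        if mmax == 0:
            continue
        # ties on |loading| (to numerical precision) break toward the last index
        k = int(np.nonzero(mags >= mmax * (1.0 - 1e-8))[0][-1])
        if v[k] < 0:
            out[:, j] = -v
    return out


def classical_mds(dm: DistanceMatrix, k: int) -> MDSResult:
    """Embed the populations in ``k`` dimensions by Torgerson scaling."""
    n = len(dm.labels)
    if not 1 <= k <= n - 1:
        raise InputError(f"k must be in [1, {n - 1}], got {k}")
    d2 = dm.d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    top = evals[:k]
    n_neg = int((top < -1e-12 * max(1.0, abs(evals[0]))).sum())
    if n_neg:
        log.warning(
            "classical_mds: %d of %d requested axes have negative eigenvalues "
            "(non-Euclidean input); their coordinates are zeroed", n_neg, k
        )
    scale = np.sqrt(np.clip(top, 0.0, None))
    coords = _fix_signs(evecs[:, :k] * scale)
    return MDSResult(
        labels=list(dm.labels),
        coords=coords,
        eigenvalues=top.copy(),
        all_eigenvalues=evals.copy(),
    )


def embedding_distortion(dm: DistanceMatrix, res: MDSResult) -> dict[str, float]:
    """Max and RMS absolute error between input and embedded distances."""
    if res.labels != dm.labels:
        raise InputError("MDS result labels do not match the distance matrix")
    diff = res.coords[:, None, :] - res.coords[None, :, :]
    dhat = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(dm.labels), k=1)
    err = np.abs(dhat[iu] - dm.d[iu])
    return {
        "max": float(err.max(initial=0.0)),
        "rms": float(np.sqrt((err**2).mean())) if err.size else 0.0,
    }
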