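"""Source-target distribution similarity via the sliced Wasserstein distance.

Transfer from a mismatched source degrades the target task (negative
transfer), so candidate source domains are ranked by how close their
feature distribution sits to the target's.  Both domains are embedded by
the same frozen extractor (by default the pooled penultimate-stage
features of a pretrained source network; raw flattened pixels as an
alternative), then the 1-Wasserstein distance between the two empirical
distributions is estimated by slicing: the exact 1-D distance averaged
over seeded random unit-vector projections.  A smaller distance means a
more similar source.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import DataError, FingerprintError, ParameterError, ShapeError

__all__ = [
    "DomainEmbedding",
    "w1_1d",
    "sliced_w1",
    "rank_sources",
    "embed_images",
]


@dataclass
class DomainEmbedding:
    """Per-image feature vectors of one domain under a stated extractor."""

    vectors: np.ndarray  # (n, d)
    domain: str
    fingerprint: str

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if len(self.vectors) == 0:
            raise DataError("embedding is empty")


def w1_1d(a, b) -> float:
    """Exact 1-D 1-Wasserstein distance between two real multisets.

    Equal sizes reduce to the mean absolute difference of sorted values;
    in general the integral of |F_a^{-1} - F_b^{-1}| is computed from the
    merged support.
    """
    a = np.sort(np.asarray(a, dtype=np.float64).ravel())
    b = np.sort(np.asarray(b, dtype=np.float64).ravel())
    if len(a) == 0 or len(b) == 0:
        raise DataError("both multisets must be non-empty")
    if len(a) == len(b):
        return float(np.abs(a - b).mean())
    # integral of |CDF_a - CDF_b| over the merged grid
    allv = np.concatenate([a, b])
    allv.sort(kind="mergesort")
    deltas = np.diff(allv)
    cdf_a = np.searchsorted(a, allv[:-1], side="right") / len(a)
    cdf_b = np.searchsorted(b, allv[:-1], side="right") / len(b)
    return float(np.sum(np.abs(cdf_a - cdf_b) * deltas))


def sliced_w1(
    a: DomainEmbedding | np.ndarray,
    b: DomainEmbedding | np.ndarray,
    n_projections: int = 256,
    seed: int = 0,
    subsample: int | None = 2000,
) -> float:
    """Sliced 1-Wasserstein distance: mean of w1_1d over random projections.

    Projections are uniform unit vectors from ``seed``; domains larger
    than ``subsample`` vectors are subsampled with the same seed.  The
    estimator is symmetric in (a, b) and zero when the vector sets match.
    """
    if n_projections < 1:
        raise ParameterError("n_projections must be >= 1")
    va = a.vectors if isinstance(a, DomainEmbedding) else np.atleast_2d(np.asarray(a, float))
    vb = b.vectors if isinstance(b, DomainEmbedding) else np.atleast_2d(np.asarray(b, float))
    if isinstance(a, DomainEmbedding) and isinstance(b, DomainEmbedding):
        if a.fingerprint != b.fingerprint:
            raise FingerprintError(
                f"embeddings from different extractors: "
                f"{a.fingerprint} != {b.fingerprint}"
            )
    if va.shape[1] != vb.shape[1]:
        raise ShapeError(f"dimension mismatch: {va.shape[1]} vs {vb.shape[1]}")
    rng = np.random.default_rng(seed)
    if subsample is not None:
        if len(va) > subsample:
            va = va[rng.choice(len(va), subsample, replace=False)]
        if len(vb) > subsample:
            vb = vb[rng.choice(len(vb), subsample, replace=False)]
    d = va.shape[1]
    total = 0.0
    for _ in range(n_projections):
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u) + 1e-300
        total += w1_1d(va @ u, vb @ u)
    return total / n_projections


def rank_sources(
    sources: dict | list,
    target: DomainEmbedding,
    n_projections: int = 256,
    seed: int = 0,
    subsample: int | None = 2000,
) -> list[dict]:
    """Rank candidate source domains by sliced-W1 distance to the target.

    ``sources`` is a mapping name -> DomainEmbedding (or a list, in which
    case ``DomainEmbedding.domain`` names them).  Returns a list of
    ``{"name", "distance", "rank", "recommended"}`` sorted ascending by
    distance, ties broken by name.
    """
    if isinstance(sources, dict):
        items = list(sources.items())
    else:
        items = [(s.domain, s) for s in sources]
    if len(items) < 2:
        raise DataError("need at least two candidate sources")
    rows = []
    for name, emb in items:
        dist = sliced_w1(emb, target, n_projections=n_projections, seed=seed,
                         subsample=subsample)
        rows.append({"name": name, "distance": dist})
    rows.sort(key=lambda r: (r["distance"], r["name"]))
    for i, r in enumerate(rows):
        r["rank"] = i + 1
        r["recommended"] = i == 0
    return rows


def embed_images(
    images: np.ndarray,
    extractor=None,
    domain: str = "",
    stage: int = -2,
) -> DomainEmbedding:
    """Embed (n, H, W, 3) images for a domain comparison.

    With ``extractor`` (a trained Source/Target model) the pooled
    activations of ``stage`` (default penultimate) are used and the
    fingerprint hashes the extractor weights; without one, raw flattened
    pixels are used.
    """
    imgs = np.asarray(images, dtype=np.float64)
    if extractor is None:
        vec = imgs.reshape(len(imgs), -1)
        fp = f"raw-pixels-{vec.shape[1]}"
        return DomainEmbedding(vectors=vec, domain=domain, fingerprint=fp)
    x = imgs.transpose(0, 3, 1, 2)
    chunk = max(1, int(2**24 / max(1, x.shape[2] * x.shape[3] * 64)))
    feats = []
    for b0 in range(0, len(x), chunk):
        pooled = extractor.net.pooled_stage_features(x[b0 : b0 + chunk])
        feats.append(pooled[stage])
    h = hashlib.sha256()
    for k in sorted(extractor.net.params):
        h.update(np.ascontiguousarray(extractor.net.params[k]).tobytes())
    fp = f"net-stage{stage}-{h.hexdigest()[:16]}"
    return DomainEmbedding(
        vectors=np.concatenate(feats, axis=0), domain=domain, fingerprint=fp
    )
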