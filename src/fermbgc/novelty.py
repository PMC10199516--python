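"""Nearest-centroid novelty queries against reference GCF collections.

BGCs are featurized as byte-capped domain-count vectors over a shared
vocabulary; each reference ecosystem (human gut / ocean / soil surrogates,
or a MIBiG/BiG-FAM-like set) is summarized by the centroids of its gene
cluster families. The Euclidean distance from a query BGC to its nearest
centroid measures novelty: distances at or above a threshold t mark novel
BGCs, and at or above a second threshold extremely divergent ones. Querying
against three ecosystems classifies each BGC as shared (close to all),
unique (far from all) or other, and the BGC x ecosystem distance matrix
feeds a principal component analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gcf import GeneClusterFamily
from .records import BgcRecord

logger = logging.getLogger(__name__)

NOVELTY_T = 900.0
NOVELTY_T_EXTREME = 1800.0
COUNT_CAP = 255


def build_vocabulary(*collections: Iterable[BgcRecord]) -> list[str]:
    """Sorted union of all domain labels across the given BGC collections."""
    vocab: set[str] = set()
    for coll in collections:
        for b in coll:
            vocab.update(b.domains)
    if not vocab:
        raise ValueError("all collections are empty: no vocabulary")
    return sorted(vocab)


def featurize(bgc: BgcRecord, vocabulary: Sequence[str]) -> np.ndarray:
    """Domain-count vector over the vocabulary, each count capped at 255.

    Labels outside the vocabulary are ignored (counted and warned about).
    """
    index = {label: i for i, label in enumerate(vocabulary)}
    v = np.zeros(len(vocabulary), dtype=float)
    unknown = 0
    for d in bgc.domains:
        i = index.get(d)
        if i is None:
            unknown += 1
        else:
            v[i] += 1
    if unknown:
        logger.warning("BGC %s: %d domains outside the vocabulary ignored", bgc.bgc_id, unknown)
    np.clip(v, 0, COUNT_CAP, out=v)
    return v


def featurize_many(bgcs: Sequence[BgcRecord], vocabulary: Sequence[str]) -> np.ndarray:
    return np.vstack([featurize(b, vocabulary) for b in bgcs]) if bgcs else np.zeros((0, len(vocabulary)))


@dataclass
class EcosystemReference:
    """Centroid summary of one reference ecosystem's GCF collection."""

    name: str
    vocabulary: tuple[str, ...]
    centroids: np.ndarray  # (n_families, vocab) — real-valued means
    centroid_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.centroids.shape != (len(self.centroid_ids), len(self.vocabulary)):
            raise ValueError(f"reference {self.name}: centroid matrix shape mismatch")


def gcf_centroids(
    name: str,
    families: Sequence[GeneClusterFamily],
    bgcs_by_id: Mapping[str, BgcRecord],
    vocabulary: Sequence[str],
) -> EcosystemReference:
    """One centroid per family: the arithmetic mean of member feature vectors."""
    if not families:
        raise ValueError(f"reference {name}: no families")
    rows = []
    ids = []
    for fam in families:
        members = [bgcs_by_id[m] for m in fam.member_bgc_ids]
        if not members:
            raise ValueError(f"family {fam.gcf_id} has zero members")
        rows.append(featurize_many(members, vocabulary).mean(axis=0))
        ids.append(fam.gcf_id)
    return EcosystemReference(name, tuple(vocabulary), np.vstack(rows), tuple(ids))


def reference_from_vectors(
    name: str, vocabulary: Sequence[str], centroids: np.ndarray, ids: Sequence[str]
) -> EcosystemReference:
    return EcosystemReference(name, tuple(vocabulary), np.asarray(centroids, float), tuple(ids))


def query_nearest(
    vector: np.ndarray, reference: EcosystemReference
) -> tuple[float, str]:
    """Euclidean distance to the nearest centroid; ties -> smallest centroid id."""
    if reference.centroids.shape[0] == 0:
        raise ValueError(f"reference {reference.name} is empty")
    d = np.linalg.norm(reference.centroids - vector, axis=1)
    best = d.min()
    # ties broken by smallest centroid id, robust to float fuzz
    tied = [reference.centroid_ids[i] for i in np.flatnonzero(d <= best)]
    return float(best), min(tied)


def calibrate_threshold(distances) -> float:
    """Novelty threshold calibrated from a bimodal distance distribution.

    The surrogate feature space has no absolute scale, so the novelty cutoff
    is derived from the data: the split that maximizes the between-class
    variance of the nearest-centroid distances (Otsu's criterion), placed at
    the midpoint between the two classes' boundary values. With distinct
    close (shared-family) and far (unshared or planted-novel) populations
    this recovers the separating threshold; on a unimodal distribution it
    degrades to an arbitrary central split and should not be trusted.
    """
    values = np.sort(np.asarray(list(distances), dtype=float))
    if values.size == 0:
        raise ValueError("no distances to calibrate on")
    uniq = np.unique(values)
    if uniq.size == 1:
        return float(uniq[0]) + 1.0
    n = values.size
    csum = np.cumsum(values)
    total = csum[-1]
    best_score, best_cut = -np.inf, uniq[0]
    # candidate splits between consecutive distinct values
    for cut_idx in np.searchsorted(values, uniq[1:], side="left"):
        n_lo = cut_idx
        n_hi = n - cut_idx
        mu_lo = csum[cut_idx - 1] / n_lo
        mu_hi = (total - csum[cut_idx - 1]) / n_hi
        score = n_lo * n_hi * (mu_lo - mu_hi) ** 2
        if score > best_score:
            best_score = score
            best_cut = (values[cut_idx - 1] + values[cut_idx]) / 2.0
    return float(best_cut)


def classify_novelty(
    distance: float, t: float = NOVELTY_T, t_extreme: float = NOVELTY_T_EXTREME
) -> str:
    """known (< t) / novel (>= t) / extremely_divergent (>= t_extreme); inclusive bounds."""
    if distance < 0:
        raise ValueError(f"distance {distance} < 0")
    if not 0 <= t <= t_extreme:
        raise ValueError("thresholds must satisfy 0 <= t <= t_extreme")
    if distance >= t_extreme:
        return "extremely_divergent"
    if distance >= t:
        return "novel"
    return "known"


def cross_ecosystem_class(distances: Mapping[str, float], t: float = NOVELTY_T) -> str:
    """unique: far (>= t) from every ecosystem; shared: close (< t) to every one; else other."""
    if not distances:
        raise ValueError("need at least one ecosystem distance")
    far = [d >= t for d in distances.values()]
    if all(far):
        return "unique"
    if not any(far):
        return "shared"
    return "other"


@dataclass
class NoveltyResult:
    bgc_id: str
    distances: dict[str, float]  # per reference name
    nearest: dict[str, str]  # per reference name -> centroid id
    novelty_class: dict[str, str]  # per reference name
    uniqueness_class: str | None = None


def query_catalog(
    bgcs: Sequence[BgcRecord],
    references: Sequence[EcosystemReference],
    vocabulary: Sequence[str],
    t: float = NOVELTY_T,
    t_extreme: float = NOVELTY_T_EXTREME,
) -> list[NoveltyResult]:
    """Query every BGC against every reference; adds the three-ecosystem
    uniqueness class when exactly three references are given."""
    if not references:
        raise ValueError("need at least one reference")
    results: list[NoveltyResult] = []
    for b in bgcs:
        v = featurize(b, vocabulary)
        distances: dict[str, float] = {}
        nearest: dict[str, str] = {}
        classes: dict[str, str] = {}
        for ref in references:
            d, cid = query_nearest(v, ref)
            distances[ref.name] = d
            nearest[ref.name] = cid
            classes[ref.name] = classify_novelty(d, t, t_extreme)
        uniq = cross_ecosystem_class(distances, t) if len(references) == 3 else None
        results.append(NoveltyResult(b.bgc_id, distances, nearest, classes, uniq))
    return results


def per_ecosystem_unique(
    results: Sequence[NoveltyResult], t: float = NOVELTY_T
) -> dict[str, set[str]]:
    """BGC ids far (>= t) from each single ecosystem (the pairwise view)."""
    out: dict[str, set[str]] = {}
    for r in results:
        for name, d in r.distances.items():
            if d >= t:
                out.setdefault(name, set()).add(r.bgc_id)
            else:
                out.setdefault(name, set())
    return out


def distance_matrix(results: Sequence[NoveltyResult]) -> tuple[np.ndarray, list[str], list[str]]:
    """(BGC x ecosystem) matrix of nearest-centroid distances."""
    names = sorted({n for r in results for n in r.distances})
    mat = np.array([[r.distances[n] for n in names] for r in results], dtype=float)
    return mat, [r.bgc_id for r in results], names


def pca_coordinates(matrix: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of a column-centered matrix.

    Returns (coordinates, explained variances), variances non-increasing.
    The sign of each axis is fixed by making its largest-magnitude loading
    positive. A constant matrix yields all-zero coordinates with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    k = int(k)
    if k < 1 or k > min(X.shape):
        raise ValueError(f"k={k} out of range for matrix {X.shape}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        logger.warning("constant matrix: PCA coordinates are all zero")
        return np.zeros((X.shape[0], k)), np.zeros(k)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U[:, :k] * s[:k]
    variances = (s**2) / max(1, X.shape[0] - 1)
    return scores, variances[:k]
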