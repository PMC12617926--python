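"""Seeded synthetic datasets with the structure the pipeline assumes.

The generator plants (i) site clusters — shared consensus host sequences and
shared semantic centroids — and (ii) a low-rank logistic association model:
sites and diseases carry latent factors aligned with the clusters and a pair's
association probability is sigma(<u_s, v_d>).  The top-probability pairs
become the validated positives, so ground-truth scores exist for every pair
and downstream recovery is well posed: the decoder's bilinear family can
represent the planted model exactly.

Defaults are the package's benchmark conditions: 80 sites, 50 diseases, 4
clusters, 300 positives, rank-4 factors, feature noise sd 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AssociationTable, NamedMatrix, SequenceRecord, ValidationError
from .features import FeatureView, MultiViewSet, ViewKind, build_disease_views, build_site_views

_BASES = np.array(list("ACGU"))

#: separation of the planted latent factors; aligned pairs sit near
#: sigma(+FACTOR_SCALE^2), unaligned pairs near sigma(0).
_FACTOR_SCALE = 2.0


@dataclass
class SynthParams:
    m: int = 80
    n: int = 50
    clusters: int = 4
    window: int = 21
    sem_dim_site: int = 16
    sem_dim_disease: int = 16
    go_dim: int = 20
    latent_rank: int = 4
    pos_count: int = 300
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clusters < 2 or self.m < self.clusters:
            raise ValidationError("need m >= clusters >= 2")
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError("window must be odd")
        if not 0 < self.pos_count <= self.m * self.n:
            raise ValidationError("pos_count must lie in (0, m*n]")
        if self.latent_rank < 1:
            raise ValidationError("latent_rank must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass
class SyntheticBundle:
    params: SynthParams
    records: list[SequenceRecord]
    site_semantic: NamedMatrix
    disease_semantic: NamedMatrix
    disease_go: NamedMatrix
    associations: AssociationTable
    site_clusters: np.ndarray
    disease_clusters: np.ndarray
    U: np.ndarray
    V: np.ndarray
    truth_scores: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        Z = self.U @ self.V.T
        self.truth_scores = 1.0 / (1.0 + np.exp(-Z))

    def site_views(self, use_alt: bool = False) -> MultiViewSet:
        return build_site_views(self.records, self.site_semantic, use_alt=use_alt)

    def disease_views(self) -> MultiViewSet:
        return build_disease_views(self.disease_go, self.disease_semantic)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    flips = rng.random(len(seq)) < rate
    for i in np.flatnonzero(flips):
        out[i] = rng.choice(_BASES[_BASES != out[i]])
    return out


def simulate_dataset(params: SynthParams | None = None) -> SyntheticBundle:
    """Complete synthetic site-disease dataset; pure function of the params."""
    p = params or SynthParams()
    rng = np.random.default_rng(p.seed)

    site_clusters = np.sort(np.arange(p.m) % p.clusters)
    disease_clusters = np.arange(p.n) % p.clusters

    # host sequences: per-cluster consensus, per-site mutations at noise_sd;
    # the alternative sequence flips the central (modified) base.
    consensi = [rng.choice(_BASES, size=p.window) for _ in range(p.clusters)]
    records = []
    for i in range(p.m):
        ref = _mutate(consensi[site_clusters[i]], p.noise_sd, rng)
        alt = ref.copy()
        c = p.window // 2
        alt[c] = rng.choice(_BASES[_BASES != ref[c]])
        records.append(SequenceRecord(f"s{i:03d}", "".join(ref), "".join(alt)))
    site_ids = [r.site_id for r in records]
    disease_ids = [f"d{j:03d}" for j in range(p.n)]

    # latent factors aligned with clusters
    centroid = np.zeros((p.clusters, p.latent_rank))
    for c in range(p.clusters):
        centroid[c, c % p.latent_rank] = _FACTOR_SCALE
    U = centroid[site_clusters] + p.noise_sd * rng.standard_normal((p.m, p.latent_rank))
    V = centroid[disease_clusters] + p.noise_sd * rng.standard_normal((p.n, p.latent_rank))

    # semantic embeddings: cluster centroid in embedding space plus noise
    site_sem_centroid = rng.standard_normal((p.clusters, p.sem_dim_site))
    site_sem = site_sem_centroid[site_clusters] + p.noise_sd * rng.standard_normal(
        (p.m, p.sem_dim_site)
    )
    proj = rng.standard_normal((p.latent_rank, p.sem_dim_disease)) / np.sqrt(p.latent_rank)
    disease_sem = V @ proj + p.noise_sd * rng.standard_normal((p.n, p.sem_dim_disease))

    # GO view: noisy cluster indicators over go_dim terms, thresholded to 0/1
    term_cluster = np.arange(p.go_dim) % p.clusters
    indicator = (term_cluster[None, :] == disease_clusters[:, None]).astype(float)
    go = (indicator + p.noise_sd * rng.standard_normal((p.n, p.go_dim)) > 0.5).astype(float)

    # positives: top pos_count pairs of the planted logistic model
    Z = U @ V.T
    flat = np.argsort(Z, axis=None)[::-1][: p.pos_count]
    rows, cols = np.unravel_index(flat, Z.shape)
    positives = {(site_ids[i], disease_ids[j]) for i, j in zip(rows, cols)}

    assoc = AssociationTable(positives, set(), site_ids, disease_ids)
    return SyntheticBundle(
        params=p,
        records=records,
        site_semantic=NamedMatrix(site_ids, site_sem),
        disease_semantic=NamedMatrix(disease_ids, disease_sem),
        disease_go=NamedMatrix(disease_ids, go),
        associations=assoc,
        site_clusters=site_clusters,
        disease_clusters=disease_clusters,
        U=U,
        V=V,
    )


def simulate_clustered_views(
    m: int,
    clusters: int,
    v: int,
    dims: tuple[int, ...],
    noise_sd: float,
    seed: int = 0,
    subspace_rank: int = 2,
) -> tuple[MultiViewSet, np.ndarray]:
    """Multi-view fixture: per cluster, an orthogonal low-dimensional subspace.

    Each view draws a random orthonormal frame and hands disjoint
    ``subspace_rank``-column blocks to the clusters, so cluster subspaces are
    exactly orthogonal; rows are subspace coefficients plus isotropic noise.
    Returns the views and the planted labels.
    """
    if len(dims) != v:
        raise ValidationError(f"{len(dims)} dims for {v} views")
    if any(d < clusters * subspace_rank for d in dims):
        raise ValidationError("each view dim must be >= clusters * subspace_rank")
    if m < clusters:
        raise ValidationError("need m >= clusters")
    rng = np.random.default_rng(seed)
    labels = np.sort(np.arange(m) % clusters)
    views = []
    for d in dims:
        Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
        rows = np.empty((m, d))
        for i in range(m):
            c = labels[i]
            basis = Q[:, c * subspace_rank : (c + 1) * subspace_rank]
            coeff = rng.standard_normal(subspace_rank)
            rows[i] = basis @ coeff
        rows += noise_sd * rng.standard_normal((m, d))
        views.append(FeatureView(ViewKind.SEMANTIC, rows))
    ids = [f"e{i:03d}" for i in range(m)]
    return MultiViewSet(ids, views), labels
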