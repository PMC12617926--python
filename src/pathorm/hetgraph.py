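"""Heterogeneous site-disease graph assembly.

The fused affinities are thresholded at tau into binary similarity blocks and
combined with the (training-fold) association block into the block adjacency

    X = [[ C~_SS , X_SD   ],
         [ X_SD^T, C~_DD ]]

of size (m+n) x (m+n).  Initial node features H^(0) stack the site semantic
embeddings over the disease semantic embeddings, zero-padded to a common
width (a learned projection is available as an alternative harmonisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import AlignmentError, AssociationTable, NamedMatrix, ValidationError
from .multiview import AffinityMatrix


class PadMode(str, Enum):
    ZERO_PAD = "zero_pad"
    LEARNED_PROJECTION = "learned_projection"


class ConfigError(ValueError):
    pass


@dataclass
class GraphConfig:
    tau: float
    feature_dim: int | None = None  # None: max of the two input widths
    pad_mode: PadMode = PadMode.ZERO_PAD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ConfigError(f"tau must lie in [0,1], got {self.tau}")
        self.pad_mode = PadMode(self.pad_mode)


@dataclass
class HeteroGraph:
    adjacency: np.ndarray
    node_features: np.ndarray
    m: int
    n: int
    site_index: list[str]
    disease_index: list[str]

    def __post_init__(self) -> None:
        t = self.m + self.n
        if self.adjacency.shape != (t, t):
            raise ValidationError(f"adjacency shape {self.adjacency.shape} != ({t},{t})")
        if self.node_features.shape[0] != t:
            raise ValidationError("node feature rows != m+n")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValidationError("adjacency must be symmetric")
        if not np.isin(self.adjacency, (0.0, 1.0)).all():
            raise ValidationError("adjacency must be binary")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValidationError("adjacency diagonal must be zero")


def threshold_affinity(C: AffinityMatrix | np.ndarray, tau: float) -> np.ndarray:
    """Binary similarity block: entry 1 iff C_ij > tau (strict), diagonal 0."""
    if not 0.0 <= tau <= 1.0:
        raise ConfigError(f"tau must lie in [0,1], got {tau}")
    vals = C.values if isinstance(C, AffinityMatrix) else np.asarray(C, dtype=float)
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValidationError("affinity entries must lie in [0,1]")
    out = (vals > tau).astype(float)
    np.fill_diagonal(out, 0.0)
    return out


def association_block(
    assoc: AssociationTable, positives: set[tuple[str, str]] | None = None
) -> np.ndarray:
    """m x n binary block from the given positives (defaults to assoc.positives).

    Passing only the training-fold positives keeps held-out pairs out of the
    graph (leakage guard).
    """
    pos = assoc.positives if positives is None else positives
    X = np.zeros((assoc.m, assoc.n))
    if pos:
        unknown = pos - assoc.positives
        if unknown:
            raise AlignmentError(f"pairs not in the association table: {sorted(unknown)[:5]}")
        idx = assoc.pair_indices(sorted(pos))
        X[idx[:, 0], idx[:, 1]] = 1.0
    return X


def harmonize_features(
    site_feats: NamedMatrix,
    disease_feats: NamedMatrix,
    config: GraphConfig,
) -> np.ndarray:
    """Stack site over disease features at a common width k0."""
    ds, dd = site_feats.values.shape[1], disease_feats.values.shape[1]
    k0 = config.feature_dim if config.feature_dim is not None else max(ds, dd)
    if config.pad_mode is PadMode.ZERO_PAD:
        if ds > k0 or dd > k0:
            raise ConfigError(
                f"feature width ({max(ds, dd)}) exceeds k0={k0} under zero_pad"
            )
        top = np.pad(site_feats.values, ((0, 0), (0, k0 - ds)))
        bot = np.pad(disease_feats.values, ((0, 0), (0, k0 - dd)))
    else:  # learned projection: fixed random Gaussian map, seeded
        rng = np.random.default_rng(config.seed)
        Ps = rng.standard_normal((ds, k0)) / np.sqrt(ds)
        Pd = rng.standard_normal((dd, k0)) / np.sqrt(dd)
        top = site_feats.values @ Ps
        bot = disease_feats.values @ Pd
    return np.vstack([top, bot])


def assemble_hetero_graph(
    C_ss: np.ndarray,
    C_dd: np.ndarray,
    assoc: AssociationTable,
    site_feats: NamedMatrix,
    disease_feats: NamedMatrix,
    config: GraphConfig,
    train_positives: set[tuple[str, str]] | None = None,
) -> HeteroGraph:
    """Block adjacency plus harmonised node features, sites first."""
    m, n = assoc.m, assoc.n
    if C_ss.shape != (m, m):
        raise AlignmentError(f"site block shape {C_ss.shape} != ({m},{m})")
    if C_dd.shape != (n, n):
        raise AlignmentError(f"disease block shape {C_dd.shape} != ({n},{n})")
    sf = site_feats.reorder(assoc.site_index)
    df = disease_feats.reorder(assoc.disease_index)
    X_sd = association_block(assoc, train_positives)
    adjacency = np.block([[C_ss, X_sd], [X_sd.T, C_dd]])
    features = harmonize_features(sf, df, config)
    return HeteroGraph(
        adjacency=adjacency,
        node_features=features,
        m=m,
        n=n,
        site_index=list(assoc.site_index),
        disease_index=list(assoc.disease_index),
    )
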