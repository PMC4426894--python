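"""The fragment transformation core.

Every query backbone triplet is rigidly superposed onto every template
triplet, giving an m x n grid of candidate transforms. Triplet pairs whose
transforms are mutually consistent (the transform of one carries the other's
query triplet close to its template triplet) are clustered by single linkage;
each surviving cluster is a local structural alignment between a query
substructure and the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateTripletError
from .structure_io import Triplet

__all__ = [
    "RigidTransform",
    "TripletPair",
    "ClusterAlignment",
    "superpose_triplet",
    "pair_distance",
    "cluster_triplet_pairs",
    "cluster_rmsd_ca",
]

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid-body motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max |R^T R - I| = {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class TripletPair:
    """A matched (query triplet, template triplet) with its transform."""

    query_index: int
    template_index: int
    transform: RigidTransform
    residual: float

    def __post_init__(self):
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class ClusterAlignment:
    """A single-linkage cluster of mutually consistent triplet pairs."""

    pairs: list[TripletPair]
    rep_transform: RigidTransform
    query_indices: list[int]
    template_indices: list[int]
    s_ca: np.ndarray  # (epsilon, 3) query Ca coordinates
    t_ca: np.ndarray  # (epsilon, 3) template Ca coordinates
    rmsd_ca: float = field(init=False)

    def __post_init__(self):
        if len(set(self.query_indices)) != len(self.query_indices):
            raise ValueError("cluster reuses a query index")
        if len(set(self.template_indices)) != len(self.template_indices):
            raise ValueError("cluster reuses a template index")
        self.rmsd_ca = cluster_rmsd_ca(self)

    @property
    def epsilon(self) -> int:
        """Number of aligned residues of the query substructure."""
        return len(self.pairs)


def _kabsch_batch(P: np.ndarray, Q: np.ndarray):
    """Least-squares proper rotations + translations for stacked point sets.

    P, Q: (B, n_atoms, 3). Returns R (B, 3, 3), t (B, 3) minimizing
    sum ||R p + t - q||^2 with det(R) = +1 (reflections corrected).
    """
    cp = P.mean(axis=1, keepdims=True)
    cq = Q.mean(axis=1, keepdims=True)
    H = np.einsum("bai,baj->bij", P - cp, Q - cq)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.transpose(0, 2, 1)
    d = np.sign(np.linalg.det(V @ U.transpose(0, 2, 1)))
    d[d == 0] = 1.0
    D = np.repeat(np.eye(3)[None], len(P), axis=0)
    D[:, 2, 2] = d
    R = V @ D @ U.transpose(0, 2, 1)
    t = cq[:, 0, :] - np.einsum("bij,bj->bi", R, cp[:, 0, :])
    return R, t


def _coords(triplet) -> np.ndarray:
    if isinstance(triplet, Triplet):
        return triplet.coords
    return np.asarray(triplet, dtype=float)


def superpose_triplet(sigma, tau) -> RigidTransform:
    """Least-squares rigid transform mapping triplet sigma onto tau.

    Minimizes the summed squared deviation over the three ordered atoms;
    reflections are excluded. Collinear triplets are rejected.
    """
    P = _coords(sigma)[None]
    Q = _coords(tau)[None]
    for X in (P, Q):
        v1 = X[0, 1] - X[0, 0]
        v2 = X[0, 2] - X[0, 1]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
            raise DegenerateTripletError("collinear triplet cannot be superposed")
    R, t = _kabsch_batch(P, Q)
    return RigidTransform(R[0], t[0])


def superposition_residual(transform: RigidTransform, sigma, tau) -> float:
    diff = transform.apply(_coords(sigma)) - _coords(tau)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=-1))))


def pair_distance(pair: TripletPair, sigma_k, tau_l, metric: str = "rmsd") -> float:
    """Distance between the target tau_l and sigma_k carried by pair's transform.

    ``metric='rmsd'`` is the 3-atom RMSD; ``metric='sum'`` is the summed
    per-atom distance.
    """
    moved = pair.transform.apply(_coords(sigma_k))
    per_atom = np.linalg.norm(moved - _coords(tau_l), axis=-1)
    if metric == "rmsd":
        return float(np.sqrt(np.mean(per_atom**2)))
    if metric == "sum":
        return float(per_atom.sum())
    raise ValueError(f"unknown metric {metric!r}")


def _pair_metric(per_atom: np.ndarray, metric: str) -> np.ndarray:
    if metric == "rmsd":
        return np.sqrt(np.mean(per_atom**2, axis=-1))
    if metric == "sum":
        return per_atom.sum(axis=-1)
    raise ValueError(f"unknown metric {metric!r}")


def _symmetrized_grid_distances(R, t, sig, tau, I, J, d0, metric, symmetric, block=512):
    """Exact symmetrized mutual distances of the transform grid, sparsely.

    A cheap necessary condition prunes first: the 3-atom RMSD is bounded
    below by the Ca displacement / sqrt(3) (and the summed distance by the
    Ca displacement), so candidate edges are found from Ca coordinates
    alone before the full 3-atom distances are evaluated. Entries that
    cannot be below d0 are +inf. Returns (sym, valid).
    """
    P = len(R)
    ca_sig = sig[:, 1, :]
    ca_tau_sel = tau[J, 1, :]  # (P, 3)
    ca_thresh2 = (3.0 if metric == "rmsd" else 1.0) * d0 * d0
    valid = (I[:, None] != I[None, :]) & (J[:, None] != J[None, :])

    cand = np.zeros((P, P), dtype=bool)
    for s in range(0, P, block):
        e = min(s + block, P)
        moved_ca = np.einsum("bij,mj->bmi", R[s:e], ca_sig) + t[s:e, None, :]
        diff = moved_ca[:, I, :] - ca_tau_sel[None, :, :]
        cand[s:e] = np.einsum("bpi,bpi->bp", diff, diff) < ca_thresh2
    cand &= valid
    if symmetric:
        # max semantics: both directions must be able to beat d0
        cand &= cand.T
    else:
        cand |= cand.T & valid

    D = np.full((P, P), np.inf)
    a_idx, b_idx = np.nonzero(cand)
    if len(a_idx):
        moved = (
            np.einsum("eij,eaj->eai", R[a_idx], sig[I[b_idx]])
            + t[a_idx][:, None, :]
        )
        per_atom = np.linalg.norm(moved - tau[J[b_idx]], axis=-1)
        D[a_idx, b_idx] = _pair_metric(per_atom, metric)
    sym = np.maximum(D, D.T) if symmetric else np.minimum(D, D.T)
    return sym, valid


def cluster_triplet_pairs(
    query_triplets,
    template_triplets,
    d0: float = 2.0,
    min_size: int = 2,
    residual_max: float = 1.0,
    symmetric: bool = True,
    metric: str = "rmsd",
    refine_transform: bool = True,
) -> list[ClusterAlignment]:
    """Single-linkage clustering of the m x n triplet-pair transform grid.

    Nodes are all (query, template) triplet pairs whose superposition
    residual is at most ``residual_max``. Two pairs with distinct query AND
    distinct template indices are linked when their (symmetrized) mutual
    transform distance is below ``d0``; clusters are the connected
    components. Within a component, one-to-one conflicts are resolved
    greedily by ascending residual (ties by (i, j) order); components with
    fewer than ``min_size`` surviving pairs are discarded. The
    representative transform is the member minimizing the total distance to
    all other members; with ``refine_transform`` it is replaced by the
    least-squares fit over all of the cluster's triplet atoms, which
    minimizes the Cartesian distance between the aligned substructures.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    sig = np.stack([_coords(x) for x in query_triplets])
    tau = np.stack([_coords(x) for x in template_triplets])
    m, n = len(sig), len(tau)
    if n < 2:
        raise ValueError("template must have at least 2 triplets")

    I_full = np.repeat(np.arange(m), n)
    J_full = np.tile(np.arange(n), m)
    R, t = _kabsch_batch(sig[I_full], tau[J_full])
    moved = np.einsum("bij,baj->bai", R, sig[I_full]) + t[:, None, :]
    resid = np.sqrt(np.mean(np.sum((moved - tau[J_full]) ** 2, axis=-1), axis=-1))

    keep = resid <= residual_max
    if not np.any(keep):
        return []
    I, J = I_full[keep], J_full[keep]
    R, t, resid = R[keep], t[keep], resid[keep]
    P = len(I)

    sym, valid = _symmetrized_grid_distances(R, t, sig, tau, I, J, d0, metric, symmetric)
    adj = valid & (sym < d0)

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    clusters: list[ClusterAlignment] = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if len(members) < min_size:
            continue
        order = sorted(members, key=lambda a: (resid[a], I[a], J[a]))
        used_i, used_j, kept = set(), set(), []
        for a in order:
            if I[a] in used_i or J[a] in used_j:
                continue
            used_i.add(I[a])
            used_j.add(J[a])
            kept.append(a)
        if len(kept) < min_size:
            continue
        kept.sort(key=lambda a: (I[a], J[a]))
        kept_arr = np.asarray(kept)
        k = len(kept_arr)
        aa = np.repeat(kept_arr, k)
        bb = np.tile(kept_arr, k)
        moved = np.einsum("eij,eaj->eai", R[aa], sig[I[bb]]) + t[aa][:, None, :]
        per_atom = np.linalg.norm(moved - tau[J[bb]], axis=-1)
        sub = _pair_metric(per_atom, metric).reshape(k, k)
        sub = np.maximum(sub, sub.T) if symmetric else np.minimum(sub, sub.T)
        totals = sub.sum(axis=1)
        rep_local = int(np.argmin(totals))  # ties: first in (i, j) order
        rep = kept[rep_local]
        if refine_transform:
            q_atoms = sig[[int(I[a]) for a in kept]].reshape(1, -1, 3)
            t_atoms = tau[[int(J[a]) for a in kept]].reshape(1, -1, 3)
            Rr, tr = _kabsch_batch(q_atoms, t_atoms)
            rep_tr = RigidTransform(Rr[0], tr[0])
        else:
            rep_tr = RigidTransform(R[rep], t[rep])
        pairs = [
            TripletPair(
                query_index=int(I[a]),
                template_index=int(J[a]),
                transform=RigidTransform(R[a], t[a]),
                residual=float(resid[a]),
            )
            for a in kept
        ]
        clusters.append(
            ClusterAlignment(
                pairs=pairs,
                rep_transform=rep_tr,
                query_indices=[int(I[a]) for a in kept],
                template_indices=[int(J[a]) for a in kept],
                s_ca=sig[[int(I[a]) for a in kept], 1, :],
                t_ca=tau[[int(J[a]) for a in kept], 1, :],
            )
        )
    clusters.sort(key=lambda c: (c.query_indices[0], c.template_indices[0]))
    return clusters


def cluster_rmsd_ca(cluster: ClusterAlignment) -> float:
    """RMSD of the cluster's query Ca atoms, carried by the representative
    transform, against the matched template Ca atoms."""
    moved = cluster.rep_transform.apply(cluster.s_ca)
    diff = moved - cluster.t_ca
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=-1))))
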