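"""Head/neck separation of a single-component spine mesh.

Per-face features are the shape diameter function (SDF; ray-cast local
thickness) and the distance to a geodesic-level-set curve skeleton.  A
two-component Gaussian mixture gives soft head/neck posteriors (the
component with the lower mean SDF is the neck), which a graph cut with a
dihedral-angle smoothness term turns into a clean binary labeling.  The
outcome also decides separability: spines whose labeling has no valid,
connected neck region containing the insertion face are "not separable".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import dijkstra, maximum_flow
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

from ._mesh import TriangleMesh, ray_first_hits
from .mesh_io import SpineMesh

log = logging.getLogger(__name__)


class NotSeparableError(RuntimeError):
    pass


@dataclass
class SegmentationParams:
    smoothing_lambda: float = 0.5
    gmm_components: int = 2
    sdf_rays: int = 25
    sdf_cone_deg: float = 120.0
    seed: int = 0
    min_region_faces: int = 5
    #: minimal GMM component separation (in pooled-SD units of the SDF axis)
    #: below which the fit is considered degenerate (no distinct neck mode)
    min_separation: float = 1.8
    #: minimal ratio of (insertion -> head/neck boundary distance) to the
    #: neck's local diameter for a labeling to count as a real neck
    min_neck_aspect: float = 0.4
    edge_weight_max: float = 10.0
    edge_weight_eps: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.smoothing_lambda <= 1.0:
            raise ValueError("smoothing_lambda must lie in [0, 1]")
        if self.gmm_components != 2:
            raise ValueError("this pipeline uses exactly 2 mixture components")


@dataclass
class Skeleton:
    nodes: np.ndarray                 # (N, 3)
    edges: np.ndarray                 # (M, 2) node-index pairs
    face_to_node: np.ndarray          # (F,)
    node_radius: np.ndarray           # (N,) mean radial spread of member vertices
    collapsed: bool = False           # sphere-like mesh, skeleton is one node

    def total_length(self) -> float:
        if len(self.edges) == 0:
            return 0.0
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).sum())

    def graph(self) -> csr_matrix:
        n = len(self.nodes)
        if len(self.edges) == 0:
            return csr_matrix((n, n))
        w = np.linalg.norm(self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]],
                           axis=1)
        g = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([self.edges[:, 0], self.edges[:, 1]]),
                         np.concatenate([self.edges[:, 1], self.edges[:, 0]]))),
                       shape=(n, n))
        return g.tocsr()

    def diameter_length(self) -> float:
        """Longest shortest-path arc length (the skeleton's main path)."""
        if len(self.nodes) <= 1 or len(self.edges) == 0:
            return 0.0
        g = self.graph()
        d0 = dijkstra(g, indices=0)
        d0 = np.where(np.isfinite(d0), d0, -1.0)
        far = int(d0.argmax())
        d1 = dijkstra(g, indices=far)
        d1 = d1[np.isfinite(d1)]
        return float(d1.max())

    def nearest_node(self, point: np.ndarray) -> int:
        return int(np.linalg.norm(self.nodes - np.asarray(point), axis=1).argmin())

    def path_length(self, a: int, b: int) -> float:
        if len(self.nodes) == 1:
            return 0.0
        dist = dijkstra(self.graph(), indices=a)
        return float(dist[b])


@dataclass
class HeadNeckLabels:
    labels: np.ndarray                # (F,) 1 = head, 0 = neck
    separable: bool
    reason: str = ""
    boundary_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def neck_mask(self) -> np.ndarray:
        return self.labels == 0


# --------------------------------------------------------------------- oriented
def oriented(mesh: TriangleMesh) -> TriangleMesh:
    """Flip all faces if the signed volume is negative (normals inward)."""
    if mesh.signed_volume() < 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy())
    return mesh


# --------------------------------------------------------------------- skeleton
def skeletonize(mesh: TriangleMesh, source_point: np.ndarray | None = None,
                n_bins: int | None = None) -> Skeleton:
    """Geodesic-level-set curve skeleton.

    Vertices are binned by geodesic distance from a source vertex (the one
    nearest ``source_point``, else an extremal vertex); each bin's connected
    groups become skeleton nodes at their centroids.  Sphere-like meshes,
    whose skeleton length does not exceed their cross-section, collapse to a
    single flagged node.
    """
    g = mesh.vertex_adjacency()
    if source_point is not None:
        src = int(np.linalg.norm(mesh.vertices - np.asarray(source_point),
                                 axis=1).argmin())
    else:
        d0 = dijkstra(g, indices=0)
        src = int(np.nanargmax(np.where(np.isfinite(d0), d0, -1)))
    dist = dijkstra(g, indices=src)
    finite = np.isfinite(dist)
    if not finite.all():
        # restrict to the source's component (callers pass single components)
        dist = np.where(finite, dist, np.nan)
    dmax = np.nanmax(dist)
    if dmax <= 0:
        return _collapsed(mesh)
    if n_bins is None:
        edge_len = g.data.mean() if g.nnz else dmax / 20.0
        n_bins = int(np.clip(np.ceil(dmax / (1.75 * edge_len)), 4, 60))
    edges_bins = np.linspace(0.0, dmax * (1 + 1e-9), n_bins + 1)
    which = np.digitize(np.nan_to_num(dist, nan=-1.0), edges_bins) - 1
    which[~finite] = -1

    nodes, radius, vert_node = [], [], np.full(mesh.n_vertices, -1, dtype=np.int64)
    gcoo = g.tocoo()
    for b in range(n_bins):
        members = np.where(which == b)[0]
        if len(members) == 0:
            continue
        # split bin into connected groups
        sel = np.isin(gcoo.row, members) & np.isin(gcoo.col, members)
        local = {v: i for i, v in enumerate(members)}
        sub = coo_matrix((np.ones(sel.sum()),
                          ([local[v] for v in gcoo.row[sel]],
                           [local[v] for v in gcoo.col[sel]])),
                         shape=(len(members), len(members)))
        _, lab = _cc(sub, directed=False)
        for grp in range(lab.max() + 1):
            vs = members[lab == grp]
            c = mesh.vertices[vs].mean(axis=0)
            nodes.append(c)
            radius.append(np.linalg.norm(mesh.vertices[vs] - c, axis=1).mean())
            vert_node[vs] = len(nodes) - 1
    nodes = np.array(nodes)
    radius = np.array(radius)

    # connect nodes joined by a mesh edge
    a = vert_node[gcoo.row]
    b = vert_node[gcoo.col]
    mask = (a >= 0) & (b >= 0) & (a != b)
    pairs = np.unique(np.sort(np.stack([a[mask], b[mask]], axis=1), axis=1), axis=0)
    skel = Skeleton(nodes=nodes, edges=pairs,
                    face_to_node=_faces_to_nodes(mesh, nodes),
                    node_radius=radius)
    # collapse test: tubular structures are much longer than they are wide
    if skel.diameter_length() < 1.15 * 2.0 * radius.max():
        return _collapsed(mesh)
    return skel


def _collapsed(mesh: TriangleMesh) -> Skeleton:
    c = mesh.vertices.mean(axis=0)
    r = float(np.linalg.norm(mesh.vertices - c, axis=1).mean())
    return Skeleton(nodes=c[None, :], edges=np.empty((0, 2), dtype=np.int64),
                    face_to_node=np.zeros(mesh.n_faces, dtype=np.int64),
                    node_radius=np.array([r]), collapsed=True)


def _faces_to_nodes(mesh: TriangleMesh, nodes: np.ndarray) -> np.ndarray:
    tree = cKDTree(nodes)
    _, idx = tree.query(mesh.face_centroids())
    return idx.astype(np.int64)


# -------------------------------------------------------------------------- SDF
def _cone_directions(n: int, half_angle: float, rng_phase: float = 0.0) -> np.ndarray:
    """Deterministic spiral of unit vectors in a cone around +z."""
    k = np.arange(n) + 0.5
    cos_t = 1.0 - (1.0 - np.cos(half_angle)) * k / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k + rng_phase
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def compute_sdf(mesh: TriangleMesh, params: SegmentationParams | None = None
                ) -> np.ndarray:
    """Per-face local diameter by interior ray casting.

    Rays are cast from each face centroid into a cone around the inward
    normal against the hole-capped mesh; per face the aggregate is the mean
    of hits within one SD of the median (outlier rejection), then one
    neighbor-smoothing pass.  Faces with no valid hit are imputed from their
    neighbors.
    """
    params = params or SegmentationParams()
    mesh = oriented(mesh)
    closed = mesh.capped()
    F = mesh.n_faces
    centroids = mesh.face_centroids()
    normals = mesh.face_normals()
    half = np.deg2rad(params.sdf_cone_deg) / 2.0
    local = _cone_directions(params.sdf_rays, half)

    # per-face orthonormal frame (e1, e2, inward normal); ray direction =
    # frame @ local spiral direction
    inward = -normals
    ref = np.where(np.abs(inward[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (F, 1)),
                   np.tile([1.0, 0.0, 0.0], (F, 1)))
    e1 = np.cross(ref, inward)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(inward, e1)
    dirs = (local[None, :, 0, None] * e1[:, None, :]
            + local[None, :, 1, None] * e2[:, None, :]
            + local[None, :, 2, None] * inward[:, None, :])

    origins = np.repeat(centroids, params.sdf_rays, axis=0) \
        - np.repeat(normals, params.sdf_rays, axis=0) * 1e-6
    exclude = np.repeat(np.arange(F), params.sdf_rays)
    t = ray_first_hits(origins, dirs.reshape(-1, 3), closed, exclude_face=exclude)
    t = t.reshape(F, params.sdf_rays)
    # a ray at angle a from the inward normal traverses a locally spherical
    # cavity over a chord of diameter*cos(a); undo that obliquity so the
    # aggregate estimates the diameter itself
    t = t / local[None, :, 2]
    # robust aggregate: a low quantile of the corrected hits; oblique rays
    # through a tube overshoot after the correction, so the lower tail is
    # the unbiased local-diameter estimate (exact for spheres and for tube
    # cross-sections), and single spuriously long rays cannot dominate
    with np.errstate(invalid="ignore"):
        tt = np.where(np.isfinite(t), t, np.nan)
        n_hits = np.isfinite(tt).sum(axis=1)
        sdf = np.nanquantile(tt, 0.15, axis=1)
        sdf[n_hits == 0] = np.nan

    adj = mesh.face_adjacency()
    nbr_sum = np.zeros(F)
    nbr_cnt = np.zeros(F)
    # impute missing values from neighbors (few passes are enough in practice)
    for _ in range(4):
        missing = np.isnan(sdf)
        if not missing.any():
            break
        filled = np.nan_to_num(sdf)
        ok = (~np.isnan(sdf)).astype(float)
        nbr_sum[:] = 0.0
        nbr_cnt[:] = 0.0
        np.add.at(nbr_sum, adj[:, 0], filled[adj[:, 1]] * ok[adj[:, 1]])
        np.add.at(nbr_sum, adj[:, 1], filled[adj[:, 0]] * ok[adj[:, 0]])
        np.add.at(nbr_cnt, adj[:, 0], ok[adj[:, 1]])
        np.add.at(nbr_cnt, adj[:, 1], ok[adj[:, 0]])
        can = missing & (nbr_cnt > 0)
        sdf[can] = nbr_sum[can] / nbr_cnt[can]
    if np.isnan(sdf).any():
        sdf[np.isnan(sdf)] = np.nanmedian(sdf)

    # one smoothing pass over the 1-ring
    nbr_sum[:] = 0.0
    nbr_cnt[:] = 0.0
    np.add.at(nbr_sum, adj[:, 0], sdf[adj[:, 1]])
    np.add.at(nbr_sum, adj[:, 1], sdf[adj[:, 0]])
    np.add.at(nbr_cnt, adj[:, 0], 1.0)
    np.add.at(nbr_cnt, adj[:, 1], 1.0)
    smooth = np.where(nbr_cnt > 0, nbr_sum / np.maximum(nbr_cnt, 1), sdf)
    return 0.5 * sdf + 0.5 * smooth


def face_features(mesh: TriangleMesh, skeleton: Skeleton,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """(F, 2) feature matrix: [sdf, distance to skeleton]."""
    sdf = compute_sdf(mesh, params)
    skel_dist = np.linalg.norm(
        mesh.face_centroids() - skeleton.nodes[skeleton.face_to_node], axis=1)
    return np.stack([sdf, skel_dist], axis=1)


# -------------------------------------------------------------------------- GMM
def ratio_penalty(ratio: float) -> float:
    """Degenerate-fit score for fits whose 'neck' is nearly as thick as the
    head (no true thin tube): forces the separation below any sane threshold."""
    return 0.0


def soft_cluster(features: np.ndarray, params: SegmentationParams | None = None
                 ) -> tuple[np.ndarray, float]:
    """Two-component GMM posteriors over {neck, head} on standardized features.

    Returns (posteriors, separation) where posteriors[:, 0] is the neck
    probability (lower-mean-SDF component) and ``separation`` is the SDF-axis
    distance between component means in pooled-SD units; a small separation
    signals a degenerate fit (single geometric population).
    """
    params = params or SegmentationParams()
    X = np.asarray(features, dtype=float)
    if len(np.unique(X, axis=0)) < 2:
        return np.full((len(X), 2), 0.5), 0.0
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # several deterministic inits (EM on these features has spurious optima
    # when a cap fan or a short neck forms a tight minority cluster); keep
    # the best-likelihood fit
    inits = []
    q10, q90 = np.quantile(Z[:, 0], [0.1, 0.9])
    lo, hi = Z[:, 0] <= q10, Z[:, 0] >= q90
    if hi.sum() == 0 or lo.sum() == 0:
        return np.full((len(X), 2), 0.5), 0.0
    inits.append(np.stack([Z[lo].mean(axis=0), Z[hi].mean(axis=0)]))
    med = np.median(Z[:, 0])
    lo, hi = Z[:, 0] <= med, Z[:, 0] > med
    if lo.sum() and hi.sum():
        inits.append(np.stack([Z[lo].mean(axis=0), Z[hi].mean(axis=0)]))
    try:
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=2, n_init=5, random_state=params.seed).fit(Z)
        inits.append(km.cluster_centers_)
    except Exception:   # pragma: no cover - k-means init is best effort
        pass
    gmm = None
    best = -np.inf
    for mi in inits:
        # generous covariance floor on the standardized features: symmetric
        # mesh regions (e.g. cap fans) yield many identical feature rows
        # that would otherwise collapse one component to a spike
        cand = GaussianMixture(n_components=2, covariance_type="full",
                               random_state=params.seed, means_init=mi,
                               reg_covar=1e-2, max_iter=200)
        cand.fit(Z)
        score = cand.score(Z)
        if score > best:
            best = score
            gmm = cand
    post = gmm.predict_proba(Z)
    # neck = component with lower mean SDF; ties broken by larger skel_dist -> head
    m = gmm.means_
    if m[0, 0] < m[1, 0] or (m[0, 0] == m[1, 0] and m[0, 1] <= m[1, 1]):
        neck_idx = 0
    else:
        neck_idx = 1
    post = post[:, [neck_idx, 1 - neck_idx]]
    var = np.array([gmm.covariances_[k][0, 0] for k in (0, 1)])
    pooled = np.sqrt(var.mean())
    separation = float(abs(m[0, 0] - m[1, 0]) / max(pooled, 1e-12))
    # mean raw SDF per component (posterior-weighted): local diameter ratio
    w = post.sum(axis=0)
    mu_neck = float((post[:, 0] * X[:, 0]).sum() / max(w[0], 1e-12))
    mu_head = float((post[:, 1] * X[:, 0]).sum() / max(w[1], 1e-12))
    ratio = mu_neck / max(mu_head, 1e-12)
    return post, separation if ratio < 0.72 else min(separation, ratio_penalty(ratio))


# -------------------------------------------------------------------- graph cut
def _edge_weights(mesh: TriangleMesh, params: SegmentationParams) -> np.ndarray:
    """Dihedral-angle smoothness weight per face-adjacency pair.

    Near-flat edges are expensive to cut (-log of the normalized normal
    angle, clamped); clearly concave creases - e.g. the head/neck junction -
    are cheap; sharp convex creases get a small constant.
    """
    adj = mesh.face_adjacency()
    n = mesh.face_normals()
    c = mesh.face_centroids()
    n1, n2 = n[adj[:, 0]], n[adj[:, 1]]
    cosa = np.clip(np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)
    alpha = np.arccos(cosa)                      # 0 = flat
    concave = np.einsum("ij,ij->i", n1, c[adj[:, 1]] - c[adj[:, 0]]) > 1e-12
    w = -np.log(np.maximum(alpha, 1e-12) / np.pi)
    w = np.clip(w, params.edge_weight_eps, params.edge_weight_max)
    sharp_convex = (~concave) & (alpha > 0.1 * np.pi)
    w[sharp_convex] = 0.2
    return w


def graph_cut_refine(mesh: TriangleMesh, posteriors: np.ndarray,
                     params: SegmentationParams | None = None) -> np.ndarray:
    """Exact binary MRF minimization by a single min s-t cut.

    Energy: sum_f -log P(label_f) + lambda * sum_{(f,g) adjacent} w(theta) *
    [label_f != label_g].  Returns labels (1 = head, 0 = neck).
    """
    params = params or SegmentationParams()
    p = np.clip(np.asarray(posteriors, dtype=float), 1e-8, 1.0 - 1e-8)
    d_neck = -np.log(p[:, 0])
    d_head = -np.log(p[:, 1])
    lam = params.smoothing_lambda
    if lam == 0.0:
        return (p[:, 1] > p[:, 0]).astype(np.int64)
    F = mesh.n_faces
    adj = mesh.face_adjacency()
    w = _edge_weights(mesh, params) * lam

    SCALE = 10_000.0
    s, t = F, F + 1
    rows = np.concatenate([np.full(F, s), np.arange(F), adj[:, 0], adj[:, 1]])
    cols = np.concatenate([np.arange(F), np.full(F, t), adj[:, 1], adj[:, 0]])
    caps = np.concatenate([d_neck, d_head, w, w])
    caps = np.maximum(1, np.round(caps * SCALE)).astype(np.int64)
    graph = coo_matrix((caps, (rows, cols)), shape=(F + 2, F + 2)).tocsr()
    res = maximum_flow(graph, s, t)
    # residual BFS from source -> source side keeps the "head" label
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = np.zeros(F + 2, dtype=bool)
    stack = [s]
    reach[s] = True
    indptr, indices, data = residual.indptr, residual.indices, residual.data
    while stack:
        u = stack.pop()
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            if data[k] > 0 and not reach[v]:
                reach[v] = True
                stack.append(v)
    return reach[:F].astype(np.int64)


def labeling_energy(mesh: TriangleMesh, posteriors: np.ndarray,
                    labels: np.ndarray, params: SegmentationParams) -> float:
    p = np.clip(np.asarray(posteriors, dtype=float), 1e-8, 1.0 - 1e-8)
    data = -np.log(np.where(labels == 1, p[:, 1], p[:, 0])).sum()
    adj = mesh.face_adjacency()
    w = _edge_weights(mesh, params)
    cut = (labels[adj[:, 0]] != labels[adj[:, 1]])
    return float(data + params.smoothing_lambda * w[cut].sum())


# ---------------------------------------------------------------------- driver
def _region_connected(mesh: TriangleMesh, mask: np.ndarray) -> bool:
    adj = mesh.face_adjacency()
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return False
    keep = mask[adj[:, 0]] & mask[adj[:, 1]]
    local = {f: i for i, f in enumerate(idx)}
    sub = coo_matrix((np.ones(keep.sum()),
                      ([local[f] for f in adj[keep, 0]],
                       [local[f] for f in adj[keep, 1]])),
                     shape=(len(idx), len(idx)))
    ncomp, _ = _cc(sub, directed=False)
    return ncomp == 1


def separate(spine: SpineMesh, params: SegmentationParams | None = None,
             skeleton: Skeleton | None = None) -> HeadNeckLabels:
    """Full head/neck separation of a single-component spine.

    separable = True (group A semantics) iff both label regions are
    non-empty (>= min_region_faces), each face-connected, and the neck
    region contains the face nearest the insertion point.
    """
    params = params or SegmentationParams()
    mesh = oriented(spine.mesh)
    if mesh.n_components() != 1:
        raise ValueError("separate() requires a single-component mesh")
    if skeleton is None:
        skeleton = skeletonize(mesh, source_point=spine.insertion_point)
    feats = face_features(mesh, skeleton, params)
    post, sep_score = soft_cluster(feats, params)
    if sep_score < params.min_separation:
        return HeadNeckLabels(labels=np.ones(mesh.n_faces, dtype=np.int64),
                              separable=False,
                              reason=f"degenerate mixture (separation {sep_score:.2f})")
    labels = graph_cut_refine(mesh, post, params)

    n_neck = int((labels == 0).sum())
    n_head = int((labels == 1).sum())
    if min(n_neck, n_head) < params.min_region_faces:
        return HeadNeckLabels(labels=labels, separable=False,
                              reason=f"region too small (neck={n_neck}, head={n_head})")
    if not _region_connected(mesh, labels == 0) or not _region_connected(mesh, labels == 1):
        return HeadNeckLabels(labels=labels, separable=False,
                              reason="label region not face-connected")
    nearest_face = int(np.linalg.norm(
        mesh.face_centroids() - spine.insertion_point, axis=1).argmin())
    if labels[nearest_face] != 0:
        return HeadNeckLabels(labels=labels, separable=False,
                              reason="insertion face not in neck region")
    adj = mesh.face_adjacency()
    adje = mesh.face_adjacency_edges()
    cut = labels[adj[:, 0]] != labels[adj[:, 1]]
    boundary = adje[cut]
    # a true neck is a tube, not a sliver at the base: the head/neck boundary
    # must sit at least ~half a local diameter away from the insertion point
    ring = mesh.vertices[np.unique(boundary)].mean(axis=0)
    neck_extent = float(np.linalg.norm(ring - spine.insertion_point))
    neck_diam = float(np.median(feats[labels == 0, 0]))
    if neck_extent < params.min_neck_aspect * neck_diam:
        return HeadNeckLabels(labels=labels, separable=False,
                              reason=f"neck region too short "
                                     f"({neck_extent:.3f} um vs local diameter "
                                     f"{neck_diam:.3f} um)")
    return HeadNeckLabels(labels=labels, separable=True,
                          boundary_edges=boundary)
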