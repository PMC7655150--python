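"""Semi-automatic skin annotation.

The annotation loop mirrors interactive labeling without the UI:
``gsc_segment`` produces a skin label from brush-stroke seeds by min-cut
energy minimization subject to geodesic star convexity (the segmented
region must be monotone along gradient-weighted geodesic paths to the star
centers); ``fit_color_models`` learns per-class Gaussian mixtures from a
finished label; ``propose_seeds`` places seeds for the next image inside
high-confidence regions using Mitchell's best-candidate (farthest point)
sampling; ``combine_annotations`` and ``agreement_score`` implement the
multi-annotator consensus (2-of-3 quorums by default).

The min-cut runs on integer-scaled capacities via
``scipy.sparse.csgraph.maximum_flow``; geodesic parents come from a
multi-source Dijkstra on the 8-connected gradient-weighted grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, maximum_flow
from skimage.color import rgb2gray
from sklearn.mixture import GaussianMixture

_CAP_SCALE = 100       # float-to-int capacity scaling
_CAP_INF = 10**7       # effectively infinite capacity (hard constraint)
_UNARY_CLAMP = 50.0    # cap on -log likelihood


@dataclass
class SeedSet:
    """Brush-stroke pixels per class; star centers are a subset of the skin
    seeds (all skin seeds by default)."""

    skin: np.ndarray        # (n, 2) (row, col)
    non_skin: np.ndarray    # (m, 2)
    star_centers: np.ndarray | None = None

    def __post_init__(self):
        self.skin = np.atleast_2d(np.asarray(self.skin, dtype=int))
        self.non_skin = np.atleast_2d(np.asarray(self.non_skin, dtype=int))
        if self.star_centers is None:
            self.star_centers = self.skin.copy()
        else:
            self.star_centers = np.atleast_2d(np.asarray(self.star_centers, dtype=int))
        a = {tuple(p) for p in self.skin}
        b = {tuple(p) for p in self.non_skin}
        if a & b:
            raise ValueError("seed classes must be disjoint")
        if not set(map(tuple, self.star_centers)) <= a:
            raise ValueError("star centers must be skin seeds")


@dataclass
class GscParams:
    lambda_pairwise: float = 5.0   # contrast-term weight (0 = unary only)
    beta: float | None = None      # contrast scale; None = mean squared diff
    k_components: int = 5          # GMM components per class
    star_convexity: bool = True
    geodesic_eps: float = 0.05     # floor on geodesic edge weights


@dataclass
class ColorModel:
    """Per-class Gaussian mixtures over pixel color."""

    skin: GaussianMixture
    non_skin: GaussianMixture

    def skin_probability(self, image: np.ndarray) -> np.ndarray:
        """Posterior skin probability per pixel (equal class priors)."""
        x = np.asarray(image, dtype=np.float64).reshape(-1, 3)
        ls = self.skin.score_samples(x)
        ln = self.non_skin.score_samples(x)
        p = 1.0 / (1.0 + np.exp(np.clip(ln - ls, -500, 500)))
        return p.reshape(np.asarray(image).shape[:2])


@dataclass
class ConsensusRule:
    n_annotators: int = 3
    pixel_quorum: int = 2
    image_quorum: int = 2

    def __post_init__(self):
        if not (1 <= self.pixel_quorum <= self.n_annotators
                and 1 <= self.image_quorum <= self.n_annotators):
            raise ValueError("quorums must lie in [1, n_annotators]")


def _fit_gmm(pixels: np.ndarray, k: int, seed: int = 0,
             reg_covar: float = 4.0) -> GaussianMixture:
    # reg_covar ~ sensor-noise variance (intensity units squared): brush
    # strokes may hold only a handful of pixels, so covariances need a
    # physically plausible floor to generalize to the unseeded region
    k_eff = min(k, len(pixels))
    if k_eff < 1:
        raise ValueError("a class has no pixels to fit")
    gm = GaussianMixture(n_components=k_eff, covariance_type="full",
                         reg_covar=reg_covar, random_state=seed, n_init=1)
    gm.fit(np.asarray(pixels, dtype=np.float64))
    return gm


def fit_color_models(image: np.ndarray, label: np.ndarray,
                     k_components: int = 5) -> ColorModel:
    """Fit per-class GMMs on the pixels of a finished skin label."""
    image = np.asarray(image)
    label = np.asarray(label, dtype=bool)
    if not label.any() or label.all():
        raise ValueError("label must contain both classes")
    pix = image.reshape(-1, 3).astype(np.float64)
    flat = label.ravel()
    if flat.sum() < k_components or (~flat).sum() < k_components:
        raise ValueError("a class has fewer pixels than mixture components")
    return ColorModel(
        skin=_fit_gmm(pix[flat], k_components, seed=0),
        non_skin=_fit_gmm(pix[~flat], k_components, seed=1),
    )


def _geodesic_parents(image: np.ndarray, centers: np.ndarray, eps: float) -> np.ndarray:
    """Geodesic parent (flat index, -1 at centers) of every pixel on the
    gradient-magnitude-weighted 8-connected grid."""
    gray = rgb2gray(np.asarray(image)) if np.asarray(image).ndim == 3 else np.asarray(image, float)
    gy, gx = np.gradient(gray.astype(np.float64))
    g = np.hypot(gy, gx)
    h, w = gray.shape
    n = h * w
    rows, cols, data = [], [], []
    idx = np.arange(n).reshape(h, w)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(max(0, -dr), h - max(0, dr))
        c0 = slice(max(0, -dc), w - max(0, dc))
        r1 = slice(max(0, dr), h + min(0, dr) or h)
        c1 = slice(max(0, dc), w + min(0, dc) or w)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        dist = np.hypot(dr, dc)
        wgt = dist * (eps + 0.5 * (g.ravel()[a] + g.ravel()[b]))
        rows.append(a); cols.append(b); data.append(wgt)
    rows = np.concatenate(rows); cols = np.concatenate(cols); data = np.concatenate(data)
    # virtual source node n connected to all star centers at zero cost
    center_idx = centers[:, 0] * w + centers[:, 1]
    rows = np.concatenate([rows, np.full(len(center_idx), n)])
    cols = np.concatenate([cols, center_idx])
    data = np.concatenate([data, np.zeros(len(center_idx))])
    graph = csr_matrix((data, (rows, cols)), shape=(n + 1, n + 1))
    _, pred = dijkstra(graph, directed=False, indices=n, return_predecessors=True)
    parents = pred[:n]
    parents[np.isin(np.arange(n), center_idx)] = -1
    parents[parents == n] = -1
    return parents


def _min_cut_labels(n: int, s_caps: np.ndarray, t_caps: np.ndarray,
                    edges: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> np.ndarray:
    """Solve the s-t min cut; returns True for nodes on the source (skin)
    side. ``edges`` are (a, b, capacity) directed arrays; s/t capacities
    are per-node."""
    src, snk = n, n + 1
    rows = [np.full(n, src), np.arange(n)]
    cols = [np.arange(n), np.full(n, snk)]
    data = [s_caps, t_caps]
    for a, b, cap in edges:
        rows.append(a); cols.append(b); data.append(cap)
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    data = np.clip(np.concatenate(data), 0, _CAP_INF).astype(np.int32)
    graph = csr_matrix((data, (rows, cols)), shape=(n + 2, n + 2))
    graph.sum_duplicates()
    res = maximum_flow(graph, src, snk)
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    # BFS from the source over positive residual capacity
    reach = np.zeros(n + 2, dtype=bool)
    stack = [src]
    reach[src] = True
    indptr, indices, rdata = residual.indptr, residual.indices, residual.data
    while stack:
        u = stack.pop()
        nbrs = indices[indptr[u]:indptr[u + 1]]
        caps = rdata[indptr[u]:indptr[u + 1]]
        for v, c in zip(nbrs, caps):
            if c > 0 and not reach[v]:
                reach[v] = True
                stack.append(v)
    return reach[:n]


def gsc_segment(image: np.ndarray, seeds: SeedSet,
                params: GscParams | None = None) -> np.ndarray:
    """Binary skin label minimizing color + boundary energy under geodesic
    star-convexity hard constraints; seed pixels keep their class."""
    params = params or GscParams()
    image = np.asarray(image)
    h, w = image.shape[:2]
    n = h * w
    if len(seeds.skin) == 0 or len(seeds.non_skin) == 0:
        raise ValueError("both seed classes must be non-empty")
    pix = image.reshape(-1, 3).astype(np.float64)
    skin_idx = seeds.skin[:, 0] * w + seeds.skin[:, 1]
    non_idx = seeds.non_skin[:, 0] * w + seeds.non_skin[:, 1]
    model = ColorModel(
        skin=_fit_gmm(pix[skin_idx], params.k_components, seed=0),
        non_skin=_fit_gmm(pix[non_idx], params.k_components, seed=1),
    )
    # unary costs: pay -log P(color | class) for the class assigned
    u_skin = np.clip(-model.skin.score_samples(pix), 0, _UNARY_CLAMP)
    u_non = np.clip(-model.non_skin.score_samples(pix), 0, _UNARY_CLAMP)
    # source side = skin: cutting s->p (p on sink side) pays the non-skin
    # cost, cutting p->t pays the skin cost
    s_caps = (u_non * _CAP_SCALE).astype(np.int64)
    t_caps = (u_skin * _CAP_SCALE).astype(np.int64)
    s_caps[skin_idx] = _CAP_INF
    t_caps[skin_idx] = 0
    t_caps[non_idx] = _CAP_INF
    s_caps[non_idx] = 0

    edges = []
    if params.lambda_pairwise > 0:
        idx = np.arange(n).reshape(h, w)
        diffs, pairs_a, pairs_b, dists = [], [], [], []
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            r0 = slice(max(0, -dr), h - max(0, dr))
            c0 = slice(max(0, -dc), w - max(0, dc))
            r1 = slice(max(0, dr), h + min(0, dr) or h)
            c1 = slice(max(0, dc), w + min(0, dc) or w)
            a = idx[r0, c0].ravel(); b = idx[r1, c1].ravel()
            pairs_a.append(a); pairs_b.append(b)
            diffs.append(((pix[a] - pix[b]) ** 2).sum(axis=1))
            dists.append(np.full(len(a), np.hypot(dr, dc)))
        a = np.concatenate(pairs_a); b = np.concatenate(pairs_b)
        d2 = np.concatenate(diffs); dist = np.concatenate(dists)
        beta = params.beta if params.beta is not None else max(d2.mean(), 1e-9)
        wgt = (params.lambda_pairwise * np.exp(-d2 / (2 * beta)) / dist
               * _CAP_SCALE).astype(np.int64)
        edges.append((a, b, wgt))
        edges.append((b, a, wgt))

    if params.star_convexity and len(seeds.star_centers):
        parents = _geodesic_parents(image, seeds.star_centers, params.geodesic_eps)
        child = np.flatnonzero(parents >= 0)
        # forbid (child = skin, parent = non-skin): infinite arc child->parent
        edges.append((child, parents[child],
                      np.full(len(child), _CAP_INF, dtype=np.int64)))

    labels = _min_cut_labels(n, s_caps, t_caps, edges)
    return labels.reshape(h, w)


def star_convexity_violations(label: np.ndarray, image: np.ndarray,
                              seeds: SeedSet, eps: float = 0.05) -> int:
    """Count pixels labeled skin whose geodesic parent is non-skin (0 for a
    geodesic-star-convex label)."""
    h, w = np.asarray(label).shape
    parents = _geodesic_parents(image, seeds.star_centers, eps)
    flat = np.asarray(label, dtype=bool).ravel()
    child = np.flatnonzero((parents >= 0) & flat)
    return int((~flat[parents[child]]).sum())


def propose_seeds(next_image: np.ndarray, model: ColorModel, n_seeds: int = 20,
                  rng_seed: int = 0, confidence_floor: float = 0.9,
                  n_candidates: int = 10) -> SeedSet:
    """Seeds for the next frame inside high-confidence probability regions,
    spread by Mitchell's best-candidate sampling (reproducible by seed)."""
    p = model.skin_probability(next_image)
    rng = np.random.default_rng(rng_seed)

    def best_candidate(region_mask: np.ndarray) -> np.ndarray:
        coords = np.argwhere(region_mask)
        if len(coords) == 0:
            raise ValueError("no pixel exceeds the confidence floor for a class")
        chosen = [coords[rng.integers(len(coords))]]
        for _ in range(min(n_seeds, len(coords)) - 1):
            cand = coords[rng.integers(len(coords), size=n_candidates)]
            d = ((cand[:, None, :] - np.array(chosen)[None]) ** 2).sum(-1).min(axis=1)
            chosen.append(cand[int(np.argmax(d))])
        return np.array(chosen)

    skin = best_candidate(p >= confidence_floor)
    non_skin = best_candidate(p <= 1.0 - confidence_floor)
    # drop accidental collisions (possible on tiny images)
    taken = {tuple(s) for s in skin}
    non_skin = np.array([q for q in non_skin if tuple(q) not in taken])
    if len(non_skin) == 0:
        raise ValueError("no non-skin seed could be placed")
    return SeedSet(skin=skin, non_skin=non_skin)


def combine_annotations(labels: Sequence[np.ndarray | None],
                        rule: ConsensusRule | None = None) -> np.ndarray | None:
    """Consensus label, or None when too few annotators supplied one.

    The image is positive iff at least ``image_quorum`` annotators supplied
    labels; a pixel is skin iff at least ``pixel_quorum`` of the suppliers
    marked it skin. Order of annotators is irrelevant.
    """
    rule = rule or ConsensusRule()
    supplied = [np.asarray(m, dtype=bool) for m in labels if m is not None]
    if len(supplied) < rule.image_quorum:
        return None
    shapes = {m.shape for m in supplied}
    if len(shapes) > 1:
        raise ValueError("annotator labels must share a grid")
    votes = np.sum(supplied, axis=0)
    return votes >= rule.pixel_quorum


def agreement_score(labels: Sequence[np.ndarray]) -> float:
    """|pixels with >= 2 votes| / |pixels with >= 1 vote| (empty union -> 1)."""
    stack = np.stack([np.asarray(m, dtype=bool) for m in labels])
    votes = stack.sum(axis=0)
    union = int((votes >= 1).sum())
    if union == 0:
        return 1.0
    return float((votes >= 2).sum() / union)
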