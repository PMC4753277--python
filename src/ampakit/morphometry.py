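"""Neuronal morphometry: SWC trees, density maps, Sholl profiles, convex
hulls, layer-resolved arbor lengths, and basket-cell subtype clustering.

Coordinate convention: morphologies live in a (lateral, depth) plane after
projection, with the pia at depth 0 and depth increasing toward the white
matter.  Cortical layer boundaries are horizontal lines at increasing depths.
Mirroring is reflection about the vertical line through the soma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

logger = logging.getLogger(__name__)

__all__ = [
    "Morphology",
    "LayerBoundaries",
    "DensityMap",
    "ShollProfile",
    "ClusterResult",
    "SWCError",
    "DegenerateHullError",
    "read_swc",
    "write_swc",
    "density_map",
    "sholl_profile",
    "convex_hull",
    "hull_area",
    "hull_fraction_above",
    "per_layer_lengths",
    "cluster_interneurons",
    "fuzzy_cmeans",
]

# SWC structure-type codes
SOMA, AXON, DENDRITE, APICAL = 1, 2, 3, 4
_TYPE_NAMES = {SOMA: "soma", AXON: "axon", DENDRITE: "dendrite",
               APICAL: "dendrite"}

LAYER_NAMES = ["L1", "L2/3", "L4", "L5", "L6"]


class SWCError(ValueError):
    pass


class DegenerateHullError(ValueError):
    pass


@dataclass
class Morphology:
    """An SWC-style tree: one row per node, parent links by id.

    ``nodes`` columns: id, type, x, y, z, radius, parent (parent -1 = root).
    x is the lateral coordinate and y the depth (pia at 0, increasing
    downward); z is kept for round-tripping but all analyses project onto
    (x, y).
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["id", "type", "x", "y", "z", "radius", "parent"]
        missing = [c for c in req if c not in self.nodes.columns]
        if missing:
            raise SWCError(f"missing SWC columns: {missing}")
        ids = set(self.nodes["id"])
        parents = set(self.nodes["parent"]) - {-1}
        dangling = parents - ids
        if dangling:
            raise SWCError(f"dangling parent ids: {sorted(dangling)[:5]}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = dict(zip(self.nodes["id"], self.nodes["parent"]))
        state: dict[int, int] = {}
        for start in parent:
            chain = []
            n = start
            while n != -1 and state.get(n, 0) == 0:
                state[n] = 1
                chain.append(n)
                n = parent[n]
            if n != -1 and state.get(n) == 1:
                raise SWCError("cycle detected in SWC parent links")
            for c in chain:
                state[c] = 2

    @property
    def soma_position(self) -> tuple[float, float]:
        soma = self.nodes[self.nodes["type"] == SOMA]
        if len(soma) == 0:
            soma = self.nodes[self.nodes["parent"] == -1]
        return float(soma["x"].mean()), float(soma["y"].mean())

    def segments(self, structure: int | None = None) -> pd.DataFrame:
        """Child/parent compartment table with Euclidean lengths.

        Each non-root node defines one compartment from its parent to itself;
        its structure type is the child's.  ``structure`` filters by type
        (APICAL counts as dendrite).
        """
        df = self.nodes.set_index("id")
        child = self.nodes[self.nodes["parent"] != -1]
        par = df.loc[child["parent"]]
        seg = pd.DataFrame(
            {
                "type": child["type"].to_numpy(),
                "x0": par["x"].to_numpy(),
                "y0": par["y"].to_numpy(),
                "z0": par["z"].to_numpy(),
                "x1": child["x"].to_numpy(),
                "y1": child["y"].to_numpy(),
                "z1": child["z"].to_numpy(),
            }
        )
        seg["length"] = np.sqrt(
            (seg.x1 - seg.x0) ** 2 + (seg.y1 - seg.y0) ** 2 + (seg.z1 - seg.z0) ** 2
        )
        if structure is not None:
            types = {structure}
            if structure == DENDRITE:
                types.add(APICAL)
            seg = seg[seg["type"].isin(types)].reset_index(drop=True)
        return seg

    def total_length(self, structure: int | None = None) -> float:
        return float(self.segments(structure)["length"].sum())

    def points(self, structure: int | None = None) -> np.ndarray:
        """2D projection (x, y) of the nodes of one structure type."""
        df = self.nodes
        if structure is not None:
            types = {structure}
            if structure == DENDRITE:
                types.add(APICAL)
            df = df[df["type"].isin(types)]
        return df[["x", "y"]].to_numpy(dtype=float)


def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
    if not rows:
        raise SWCError(f"{path}: no nodes")
    nodes = pd.DataFrame(
        rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]
    )
    return Morphology(nodes=nodes)


def write_swc(morph: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in morph.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.id)} {int(row.type)} {row.x:.6g} {row.y:.6g} "
                f"{row.z:.6g} {row.radius:.6g} {int(row.parent)}\n"
            )


@dataclass(frozen=True)
class LayerBoundaries:
    """Depths (um) of the four boundaries between neocortical layers 1-6."""

    l1_l23: float
    l23_l4: float
    l4_l5: float
    l5_l6: float

    def __post_init__(self) -> None:
        seq = (self.l1_l23, self.l23_l4, self.l4_l5, self.l5_l6)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("layer boundary depths must be strictly increasing")
        if self.l1_l23 <= 0:
            raise ValueError("boundaries are depths below the pia (> 0)")

    @property
    def edges(self) -> np.ndarray:
        return np.asarray([self.l1_l23, self.l23_l4, self.l4_l5, self.l5_l6])


@dataclass
class DensityMap:
    """Averaged 2D arbor-density map over (lateral, depth).

    ``grid`` is the linear (pre-gamma) average of per-cell maps, each mirrored
    about its soma's vertical axis and normalised to unit maximum; ``display``
    applies the gamma exponent.  ``lateral`` / ``depth`` are the bin-centre
    axes, with depth expressed relative to the L4/L5 boundary (negative = more
    superficial).
    """

    grid: np.ndarray
    lateral: np.ndarray
    depth: np.ndarray
    sigma: float
    gamma: float

    @property
    def display(self) -> np.ndarray:
        return np.power(self.grid, self.gamma)

    def to_csv(self, path, meta_path=None) -> None:
        np.savetxt(path, self.grid, delimiter=",")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                fh.write(f"sigma_um,{self.sigma}\n")
                fh.write(f"gamma,{self.gamma}\n")
                fh.write(f"lateral_min_um,{self.lateral[0]}\n")
                fh.write(f"lateral_step_um,{self.lateral[1]-self.lateral[0]}\n")
                fh.write(f"depth_min_um,{self.depth[0]}\n")
                fh.write(f"depth_step_um,{self.depth[1]-self.depth[0]}\n")


def _single_cell_map(
    seg: pd.DataFrame,
    soma_x: float,
    lateral: np.ndarray,
    depth: np.ndarray,
    bin_um: float,
    sigma: float,
    mirror: bool,
) -> np.ndarray:
    """Sum of per-compartment Gaussians on the grid (rows = depth).

    Compartments are represented by their midpoints with mass equal to their
    length; the Gaussian blur is applied by convolution, which preserves
    total mass on a sufficiently padded grid.
    """
    if len(seg) == 0:
        return np.zeros((len(depth), len(lateral)))
    mx = 0.5 * (seg.x0 + seg.x1).to_numpy()
    my = 0.5 * (seg.y0 + seg.y1).to_numpy()
    w = seg.length.to_numpy()
    xedges = np.concatenate([lateral - bin_um / 2, [lateral[-1] + bin_um / 2]])
    yedges = np.concatenate([depth - bin_um / 2, [depth[-1] + bin_um / 2]])
    hist, _, _ = np.histogram2d(my, mx, bins=(yedges, xedges), weights=w)
    m = gaussian_filter(hist, sigma=sigma / bin_um, mode="constant")
    if mirror:
        # reflect about the vertical line through the soma
        shift = soma_x - lateral
        mirrored = np.empty_like(m)
        for r in range(m.shape[0]):
            mirrored[r] = np.interp(2 * soma_x - lateral, lateral, m[r],
                                    left=0.0, right=0.0)
        m = 0.5 * (m + mirrored)
    return m


def density_map(
    morphs: list[Morphology],
    boundaries: LayerBoundaries,
    structure: int = AXON,
    sigma: float = 25.0,
    gamma: float = 0.5,
    bin_um: float = 5.0,
    extent: float = 600.0,
    mirror: bool = True,
    normalize: bool = True,
) -> DensityMap:
    """Ensemble arbor-density map for one structure type.

    Each compartment contributes a 2D Gaussian of mass equal to its length
    (sigma fixed, 25 um default).  Per-cell maps are centred on the L4/L5
    boundary (depth axis) and the soma (lateral axis), mirrored about the
    soma's vertical axis, normalised to unit maximum and averaged; the gamma
    exponent is display-only.  ``extent`` sets the half-width of the map in
    um.  With ``normalize=False`` (single-cell use) the raw mass-preserving
    sum is returned instead.
    """
    half = extent
    lateral = np.arange(-half, half + bin_um / 2, bin_um)
    depth = np.arange(-half, half + bin_um / 2, bin_um)
    acc = np.zeros((len(depth), len(lateral)))
    n_used = 0
    for morph in morphs:
        seg = morph.segments(structure)
        if len(seg) == 0:
            continue
        sx, _ = morph.soma_position
        seg = seg.copy()
        # centre: soma laterally, L4/L5 boundary in depth
        seg[["x0", "x1"]] -= sx
        seg[["y0", "y1"]] -= boundaries.l4_l5
        m = _single_cell_map(seg, 0.0, lateral, depth, bin_um, sigma, mirror)
        if normalize:
            peak = m.max()
            if peak > 0:
                m = m / peak
        acc += m
        n_used += 1
    if n_used:
        acc /= n_used
    return DensityMap(grid=acc, lateral=lateral, depth=depth, sigma=sigma,
                      gamma=gamma)


@dataclass
class ShollProfile:
    radii: np.ndarray                  # um
    crossings: dict[str, np.ndarray]   # per structure name

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"radius_um": self.radii})
        for k, v in self.crossings.items():
            df[k] = v
        return df


def sholl_profile(morph: Morphology, step: float = 6.5) -> ShollProfile:
    """Counts of compartments straddling concentric circles around the soma.

    A compartment straddles radius r when its two endpoint distances to the
    soma lie on opposite sides of r (half-open: d_min <= r < d_max, so a
    compartment is counted once at a radius equal to its proximal endpoint).
    Radii run in ``step`` (6.5 um default) increments to past the arbor.
    """
    sx, sy = morph.soma_position
    out: dict[str, np.ndarray] = {}
    max_d = 0.0
    seg_by_type = {}
    for stype, name in ((AXON, "axon"), (DENDRITE, "dendrite")):
        seg = morph.segments(stype)
        if len(seg):
            d0 = np.hypot(seg.x0.to_numpy() - sx, seg.y0.to_numpy() - sy)
            d1 = np.hypot(seg.x1.to_numpy() - sx, seg.y1.to_numpy() - sy)
            seg_by_type[name] = (np.minimum(d0, d1), np.maximum(d0, d1))
            max_d = max(max_d, float(d1.max()), float(d0.max()))
        else:
            seg_by_type[name] = (np.empty(0), np.empty(0))
    radii = np.arange(step, max_d + 2 * step, step)
    for name, (dmin, dmax) in seg_by_type.items():
        if len(dmin):
            out[name] = np.count_nonzero(
                (dmin[None, :] <= radii[:, None]) & (radii[:, None] < dmax[None, :]),
                axis=1,
            )
        else:
            out[name] = np.zeros(len(radii), dtype=int)
    return ShollProfile(radii=radii, crossings=out)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Gift-wrapping (Jarvis-march) convex hull of 2D points.

    Returns hull vertices in counter-clockwise order; collinear points on a
    hull edge are not vertices.  Fewer than 3 non-collinear points raise
    ``DegenerateHullError``.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise DegenerateHullError("need at least 3 distinct points")
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]  # leftmost (lowest on ties)
    hull = [start]
    current = start
    while True:
        candidate = (current + 1) % len(pts)
        for j in range(len(pts)):
            if j == current:
                continue
            u = pts[candidate] - pts[current]
            w = pts[j] - pts[current]
            cross = u[0] * w[1] - u[1] * w[0]
            if cross < 0 or (
                cross == 0
                and np.linalg.norm(pts[j] - pts[current])
                > np.linalg.norm(pts[candidate] - pts[current])
            ):
                candidate = j
        current = candidate
        if current == start:
            break
        hull.append(current)
        if len(hull) > len(pts):  # defensive: should not happen
            raise DegenerateHullError("hull construction failed to close")
    verts = pts[hull]
    if len(verts) < 3 or hull_area(verts) == 0:
        raise DegenerateHullError("all points are collinear (zero-area hull)")
    # gift wrapping with clockwise selection (cross < 0) yields CW order;
    # flip to counter-clockwise
    if _signed_area(verts) < 0:
        verts = verts[::-1]
    return verts


def _signed_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(
        np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    )


def hull_area(verts: np.ndarray) -> float:
    return abs(_signed_area(np.asarray(verts, dtype=float)))


def ensemble_hull(hulls: list[np.ndarray], mirror_axis: float | None = None
                  ) -> np.ndarray:
    """Convex hull of the union of per-cell hulls and their mirror images."""
    pts = []
    for h in hulls:
        pts.append(h)
        if mirror_axis is not None:
            m = h.copy()
            m[:, 0] = 2 * mirror_axis - m[:, 0]
            pts.append(m)
    return convex_hull(np.vstack(pts))


def hull_fraction_above(hull: np.ndarray, boundary_depth: float) -> float:
    """Area fraction of a hull on the pial side of a horizontal boundary.

    Depth increases away from the pia, so "above" means depth smaller than
    ``boundary_depth``.  Exact polygon clipping via shapely.
    """
    poly = Polygon(np.asarray(hull, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise DegenerateHullError("degenerate hull")
    minx, miny, maxx, maxy = poly.bounds
    if boundary_depth <= miny:
        return 0.0
    if boundary_depth >= maxy:
        return 1.0
    pad = 1.0
    clip = box(minx - pad, miny - pad, maxx + pad, boundary_depth)
    return float(poly.intersection(clip).area / poly.area)


def per_layer_lengths(
    morph: Morphology, boundaries: LayerBoundaries
) -> pd.DataFrame:
    """Axon/dendrite arbor length apportioned to cortical layers.

    Each compartment's length is split between layers in proportion to the
    fraction of its depth extent inside each band; compartments beyond the
    defined boundaries count toward the outermost layers (L1 above the pia
    band, L6 below), with a logged warning.
    """
    edges = np.concatenate([[-np.inf], boundaries.edges, [np.inf]])
    out = {name: {"axon": 0.0, "dendrite": 0.0} for name in LAYER_NAMES}
    warned = False
    for stype, name in ((AXON, "axon"), (DENDRITE, "dendrite")):
        seg = morph.segments(stype)
        if len(seg) == 0:
            continue
        y0 = np.minimum(seg.y0, seg.y1).to_numpy()
        y1 = np.maximum(seg.y0, seg.y1).to_numpy()
        L = seg.length.to_numpy()
        if not warned and (np.any(y0 < 0) or np.any(y1 > boundaries.l5_l6)):
            logger.warning("morphology extends beyond the defined layer "
                           "boundaries; assigned to the outermost layers")
            warned = True
        span = np.where(y1 > y0, y1 - y0, 1.0)
        for li, lname in enumerate(LAYER_NAMES):
            lo, hi = edges[li], edges[li + 1]
            overlap = np.clip(np.minimum(y1, hi) - np.maximum(y0, lo), 0.0, None)
            frac = np.where(
                y1 > y0,
                overlap / span,
                ((y0 >= lo) & (y0 < hi)).astype(float),  # horizontal segment
            )
            out[lname][name] += float(np.dot(frac, L))
    return pd.DataFrame(
        [
            {"layer": lname, "axon_um": out[lname]["axon"],
             "dendrite_um": out[lname]["dendrite"]}
            for lname in LAYER_NAMES
        ]
    )


@dataclass
class ClusterResult:
    features: np.ndarray        # one value per cell
    linkage: np.ndarray         # scipy linkage matrix (single, sq. Euclidean)
    cut_height: float           # 0.25 * max merge height
    labels: np.ndarray          # hierarchical labels at the cut (1-based)
    fcm_labels: np.ndarray      # fuzzy c-means hard labels (c = 2)
    fcm_memberships: np.ndarray  # (n, 2) membership matrix
    agreement: float            # best-permutation label agreement in [0, 1]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "cluster": self.labels,
                "fcm_cluster": self.fcm_labels,
            }
        )


def fuzzy_cmeans(
    x: np.ndarray, c: int = 2, m: float = 2.0, tol: float = 1e-8,
    max_iter: int = 300, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Plain fuzzy c-means on a 1D feature; returns (centers, memberships)."""
    x = np.asarray(x, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    # deterministic spread initialisation plus a nudge for exact ties
    centers = np.quantile(x, np.linspace(0.1, 0.9, c)) + rng.normal(0, 1e-9, c)
    u = np.full((len(x), c), 1.0 / c)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        w = u_new**m
        centers_new = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            centers = centers_new
            break
        u, centers = u_new, centers_new
    return centers, u


def cluster_interneurons(features) -> ClusterResult:
    """Basket-cell subtype clustering on one feature per cell.

    Agglomerative single-linkage clustering with the squared Euclidean
    distance, cut at 25% of the maximum merge height (clusters = connected
    components below the cut).  A fuzzy c-means run with c = 2 provides an
    independent check; ``agreement`` is the best-permutation fraction of
    cells labelled the same way by both methods.
    """
    x = np.asarray(features, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 cells to cluster")
    d = (x[:, None] - x[None, :]) ** 2
    condensed = d[np.triu_indices(len(x), k=1)]
    Z = hierarchy.linkage(condensed, method="single")
    hmax = float(Z[:, 2].max())
    cut = 0.25 * hmax
    if hmax == 0:
        labels = np.ones(len(x), dtype=int)
    else:
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    _, u = fuzzy_cmeans(x, c=2)
    fcm = u.argmax(axis=1) + 1
    agreement = _best_agreement(labels, fcm)
    return ClusterResult(
        features=x,
        linkage=Z,
        cut_height=cut,
        labels=labels,
        fcm_labels=fcm,
        fcm_memberships=u,
        agreement=agreement,
    )


def _best_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of matching labels under the best label permutation of b."""
    from itertools import permutations

    la, lb = np.unique(a), np.unique(b)
    best = 0.0
    for perm in permutations(lb, min(len(lb), len(la))) or [()]:
        mapping = dict(zip(perm, la))
        mapped = np.array([mapping.get(v, -1) for v in b])
        best = max(best, float(np.mean(mapped == a)))
    return best
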