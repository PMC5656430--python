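"""Registration of imaged ROIs to the canonical neuron map.

The layout of identified neurons within a leech ganglion is well
conserved but geometrically variable, so imaged cells are matched to the
canonical chart in three steps, per aspect:

1. **Coarse alignment** — from user-confirmed (ROI, neuron) pairs, an
   affine map ``M = T2 . S2 . R . S1 . T1`` is fitted per glial packet
   (T1/T2 translations centering the two point sets, S1 an isotropic
   scale matching their spreads, R a rotation fitted by orthogonal
   Procrustes, S2 an anisotropic scale compensating residual stretch);
   packets with too few anchors inherit the whole-aspect transform.
2. **Fine alignment** — the residual mismatches at the confirmed pairs
   define a Gaussian-kernel displacement field
   ``dX(X,Y) = sum_k dX_k exp(-((X-X_k)^2 + (Y-Y_k)^2) / (2 sigma_k^2))``
   with ``sigma_k`` set to sqrt(3) times the distance from the k-th
   anchor ROI to its nearest neighboring ROI, so user identities are
   respected geometrically and nearby cells follow local geometry.
3. **Automatic assignment** — remaining neurons are mapped to nearby ROIs
   one-to-one; conflicts are resolved by a cost that treats size-matched
   pairs as most meritorious and penalizes displacement of large cells
   more than of small cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .synthgen import CanonicalMap
from .traces import ROISet

__all__ = [
    "PacketTransform",
    "WarpField",
    "AssignmentMap",
    "coarse_align",
    "fine_align",
    "auto_assign",
    "register",
    "iterate_registration",
    "CanonicalRegistration",
    "plot_overlay",
]


class DegenerateInputError(ValueError):
    """Anchor geometry does not determine a transform."""


# ---------------------------------------------------------------------------
# Coarse alignment
# ---------------------------------------------------------------------------

@dataclass
class PacketTransform:
    """Affine map M = T2 . S2 . R . S1 . T1 from canonical to image space."""

    packet: int | None          # None = whole-aspect fallback transform
    t1: np.ndarray              # (2,) translation applied first
    s1: float                   # isotropic scale
    r: np.ndarray               # (2, 2) rotation, det = +1
    s2: np.ndarray              # (2,) anisotropic scale
    t2: np.ndarray              # (2,) translation applied last

    def __post_init__(self) -> None:
        if self.s1 <= 0 or np.any(self.s2 <= 0):
            raise DegenerateInputError("scales must be strictly positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = (p + self.t1) * self.s1
        q = q @ self.r.T
        q = q * self.s2
        return q + self.t2

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.r[1, 0], self.r[0, 0])))

    @property
    def mean_scale(self) -> float:
        """Isotropic magnification of the linear part (for size conversion)."""
        return float(self.s1 * np.sqrt(float(self.s2[0] * self.s2[1])))


def _fit_transform(c: np.ndarray, r: np.ndarray, packet: int | None
                   ) -> PacketTransform:
    """Fit the staged affine map from canonical points c to ROI points r."""
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    t1 = -c.mean(axis=0)
    t2 = r.mean(axis=0)
    c0 = c + t1
    r0 = r - t2
    spread_c = np.sqrt((c0 ** 2).sum(axis=1).mean())
    spread_r = np.sqrt((r0 ** 2).sum(axis=1).mean())
    if spread_c <= 0 or spread_r <= 0:
        raise DegenerateInputError("anchor points have zero spread")
    s1 = spread_r / spread_c
    a = s1 * c0

    def _procrustes(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        # orthogonal Procrustes restricted to det = +1 (no reflection)
        u, _, vt = np.linalg.svd(src.T @ dst)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        return vt.T @ np.diag([1.0, d]) @ u.T

    def _diag_scale(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        # per-coordinate least squares, identity fallback
        s = np.ones(2)
        for j in range(2):
            denom = float(src[:, j] @ src[:, j])
            if denom > 0:
                sj = float(src[:, j] @ dst[:, j]) / denom
                if sj > 0:
                    s[j] = sj
        return s

    rot = _procrustes(a, r0)
    s2 = _diag_scale(a @ rot.T, r0)
    # the rotation fitted before the stretch is biased when the true
    # distortion applies the stretch after rotating; a few alternating
    # refinements converge to the exact factorization on clean data
    for _ in range(10):
        rot_new = _procrustes(a, r0 / s2)
        s2_new = _diag_scale(a @ rot_new.T, r0)
        if np.allclose(rot_new, rot, atol=1e-12) and \
                np.allclose(s2_new, s2, atol=1e-12):
            rot, s2 = rot_new, s2_new
            break
        rot, s2 = rot_new, s2_new
    return PacketTransform(packet=packet, t1=t1, s1=float(s1), r=rot,
                           s2=s2, t2=t2)


def _collinear(points: np.ndarray) -> bool:
    p = points - points.mean(axis=0)
    sv = np.linalg.svd(p, compute_uv=False)
    return sv[-1] < 1e-9 * max(sv[0], 1.0)


def coarse_align(user_pairs: pd.DataFrame, canonical: CanonicalMap,
                 rois: ROISet, min_pairs: int = 3
                 ) -> dict[int | None, PacketTransform]:
    """Fit per-packet affine transforms from confirmed (roi, neuron) pairs.

    ``user_pairs`` needs columns ``roi_id`` and ``neuron_id``.  Packets
    with at least ``min_pairs`` non-collinear anchors get their own
    transform; the remainder share the whole-aspect transform fitted on
    all pairs (key ``None``).
    """
    centers = _roi_centers(rois)
    pairs = user_pairs.reset_index(drop=True)
    if pairs["roi_id"].duplicated().any() or pairs["neuron_id"].duplicated().any():
        raise ValueError("contradictory user pairs: an ROI or neuron repeats")
    c_all, r_all, packets = [], [], []
    for _, row in pairs.iterrows():
        n = canonical[str(row["neuron_id"])]
        c_all.append((n.x, n.y))
        r_all.append(centers[str(row["roi_id"])])
        packets.append(n.packet)
    c_all = np.asarray(c_all)
    r_all = np.asarray(r_all)
    if len(c_all) < min_pairs or _collinear(c_all) or _collinear(r_all):
        raise DegenerateInputError(
            "need at least 3 non-collinear confirmed pairs for the "
            "whole-aspect transform")
    out: dict[int | None, PacketTransform] = {
        None: _fit_transform(c_all, r_all, None)}
    for pk in sorted(set(packets)):
        sel = np.array([p == pk for p in packets])
        if sel.sum() >= min_pairs and not _collinear(c_all[sel]) \
                and not _collinear(r_all[sel]):
            out[pk] = _fit_transform(c_all[sel], r_all[sel], pk)
    return out


def _roi_centers(rois: ROISet) -> dict[str, np.ndarray]:
    centers = {}
    for roi in rois:
        if roi.ellipse is not None:
            centers[roi.id] = np.array(roi.ellipse[:2], dtype=float)
        else:
            centers[roi.id] = np.asarray(roi.polygon, dtype=float).mean(axis=0)
    return centers


def _roi_radii(rois: ROISet) -> dict[str, float]:
    radii = {}
    for roi in rois:
        if roi.ellipse is not None:
            radii[roi.id] = float(np.sqrt(roi.ellipse[2] * roi.ellipse[3]))
        else:
            p = np.asarray(roi.polygon, dtype=float)
            radii[roi.id] = float(np.sqrt(
                ((p - p.mean(axis=0)) ** 2).sum(axis=1).mean()))
    return radii


def _transform_for(packet: int,
                   transforms: dict[int | None, PacketTransform]
                   ) -> PacketTransform:
    return transforms.get(packet, transforms[None])


# ---------------------------------------------------------------------------
# Fine alignment
# ---------------------------------------------------------------------------

@dataclass
class WarpField:
    """Gaussian-kernel displacement field built from anchor residuals."""

    anchors_xy: np.ndarray      # (k, 2) ROI centers of the confirmed pairs
    residuals: np.ndarray       # (k, 2) actual minus affine-predicted coords
    sigmas: np.ndarray          # (k,) kernel scales

    def __post_init__(self) -> None:
        if np.any(self.sigmas <= 0):
            raise DegenerateInputError("kernel scales must be > 0")

    def delta(self, points: np.ndarray) -> np.ndarray:
        """Displacement (dX, dY) at the given points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if len(self.anchors_xy) == 0:
            return np.zeros_like(p)
        d2 = ((p[:, None, :] - self.anchors_xy[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * d2 / self.sigmas[None, :] ** 2)
        return w @ self.residuals


def fine_align(user_pairs: pd.DataFrame, canonical: CanonicalMap,
               rois: ROISet,
               transforms: dict[int | None, PacketTransform]) -> WarpField:
    """Build the residual displacement field from the confirmed pairs."""
    centers = _roi_centers(rois)
    xy, res = [], []
    for _, row in user_pairs.iterrows():
        n = canonical[str(row["neuron_id"])]
        m = _transform_for(n.packet, transforms)
        pred = m.apply([(n.x, n.y)])[0]
        actual = centers[str(row["roi_id"])]
        xy.append(actual)
        res.append(actual - pred)
    xy = np.asarray(xy, dtype=float)
    res = np.asarray(res, dtype=float)
    if len(xy) == 0:
        raise ValueError("at least one confirmed pair is required")
    if len(xy) > 1:
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        if np.any(d.min(axis=1) <= 0):
            raise DegenerateInputError("coincident anchors: sigma undefined")
    # sigma_k = sqrt(3) x the distance from the k-th (anchor) ROI to its
    # nearest neighboring ROI in the full ROI set: warps stay local at the
    # scale of the cell spacing even where anchors are sparse
    all_xy = np.asarray(list(centers.values()))
    sigmas = np.empty(len(xy))
    for k, p in enumerate(xy):
        dd = np.sqrt(((all_xy - p) ** 2).sum(axis=1))
        dd = dd[dd > 1e-12]
        sigmas[k] = (np.sqrt(3.0) * dd.min() if dd.size
                     else np.sqrt(3.0) * _median_nn_distance(all_xy))
    return WarpField(anchors_xy=xy, residuals=res, sigmas=sigmas)


def _median_nn_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 1.0
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


# ---------------------------------------------------------------------------
# Automatic assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentMap:
    """One-to-one ROI <-> neuron correspondence with provenance."""

    pairs: pd.DataFrame                 # roi_id, neuron_id, provenance,
                                        # displacement_px, size_ratio, cost
    unassigned_rois: list[str] = field(default_factory=list)
    unassigned_neurons: list[str] = field(default_factory=list)
    transforms: dict | None = None
    warp: WarpField | None = None

    def __post_init__(self) -> None:
        if self.pairs["roi_id"].duplicated().any() or \
                self.pairs["neuron_id"].duplicated().any():
            raise ValueError("assignment must be one-to-one")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["roi_id"], self.pairs["neuron_id"]))


def _warped_positions(canonical: CanonicalMap,
                      transforms: dict[int | None, PacketTransform],
                      warp: WarpField | None) -> dict[str, np.ndarray]:
    out = {}
    for n in canonical.neurons:
        m = _transform_for(n.packet, transforms)
        p = m.apply([(n.x, n.y)])[0]
        if warp is not None:
            p = p + warp.delta(p[None])[0]
        out[n.id] = p
    return out


def auto_assign(canonical: CanonicalMap, rois: ROISet,
                transforms: dict[int | None, PacketTransform],
                warp: WarpField | None,
                user_pairs: pd.DataFrame | None = None,
                n_candidates: int = 5,
                small_component: int = 8) -> AssignmentMap:
    """Assign remaining neurons to nearby ROIs, one-to-one.

    Each neuron not confirmed by the user proposes its nearest ROIs in
    warped image space.  Conflicts are resolved by the cost

        cost(n, r) = ||displacement||^2 * radius_n / median_radius
                     + lambda * (log radius_n - log radius_r)^2,

    with ``lambda`` the squared median nearest-neighbor ROI distance:
    size-similar matches are most meritorious and displacing larger cells
    costs more.  Small conflict components (both sides <= 8) are resolved
    by optimal assignment, larger ones greedily lowest-cost-first.  User
    pairs are preserved verbatim; unresolvable items are listed, never
    dropped.
    """
    centers = _roi_centers(rois)
    radii = _roi_radii(rois)
    user_pairs = user_pairs if user_pairs is not None else pd.DataFrame(
        columns=["roi_id", "neuron_id"])
    used_rois = set(user_pairs["roi_id"].astype(str))
    used_neurons = set(user_pairs["neuron_id"].astype(str))

    pos = _warped_positions(canonical, transforms, warp)
    free_neurons = [n for n in canonical.neurons if n.id not in used_neurons]
    free_rois = [rid for rid in centers if rid not in used_rois]

    rows = [
        {"roi_id": str(r), "neuron_id": str(n), "provenance": "user",
         "displacement_px": float(np.linalg.norm(
             centers[str(r)] - pos[str(n)])),
         "size_ratio": radii[str(r)] / max(
             canonical[str(n)].radius * transforms[None].mean_scale, 1e-9),
         "cost": 0.0}
        for r, n in zip(user_pairs["roi_id"], user_pairs["neuron_id"])
    ]

    if free_neurons and free_rois:
        roi_xy = np.asarray([centers[r] for r in free_rois])
        tree = cKDTree(roi_xy)
        med_nn = _median_nn_distance(np.asarray(list(centers.values())))
        lam = med_nn ** 2
        med_rad = float(np.median([n.radius for n in canonical.neurons]))
        scale = transforms[None].mean_scale
        k = min(n_candidates, len(free_rois))
        cand: list[tuple[float, int, int]] = []   # (cost, neuron_idx, roi_idx)
        for ni, neuron in enumerate(free_neurons):
            d, idx = tree.query(pos[neuron.id], k=k)
            d = np.atleast_1d(d)
            idx = np.atleast_1d(idx)
            for dist, ri in zip(d, idx):
                r_rad = radii[free_rois[ri]]
                n_rad = max(neuron.radius * scale, 1e-9)
                cost = (dist ** 2 * neuron.radius / med_rad
                        + lam * np.log(max(n_rad, 1e-9) / max(r_rad, 1e-9)) ** 2)
                cand.append((float(cost), ni, int(ri)))

        assigned = _resolve_conflicts(cand, len(free_neurons), len(free_rois),
                                      small_component)
        for ni, ri in assigned:
            neuron = free_neurons[ni]
            rid = free_rois[ri]
            cost = next(c for c, a, b in cand if a == ni and b == ri)
            rows.append({
                "roi_id": rid, "neuron_id": neuron.id,
                "provenance": "automatic",
                "displacement_px": float(np.linalg.norm(
                    centers[rid] - pos[neuron.id])),
                "size_ratio": radii[rid] / max(neuron.radius * scale, 1e-9),
                "cost": cost,
            })

    pairs = pd.DataFrame(rows, columns=["roi_id", "neuron_id", "provenance",
                                        "displacement_px", "size_ratio",
                                        "cost"])
    taken_r = set(pairs["roi_id"])
    taken_n = set(pairs["neuron_id"])
    return AssignmentMap(
        pairs=pairs,
        unassigned_rois=[r for r in centers if r not in taken_r],
        unassigned_neurons=[n.id for n in canonical.neurons
                            if n.id not in taken_n],
        transforms=transforms, warp=warp)


def _resolve_conflicts(cand: list[tuple[float, int, int]], n_neurons: int,
                       n_rois: int, small: int) -> list[tuple[int, int]]:
    """One-to-one matching over the candidate graph.

    Connected components with both sides at most ``small`` are solved
    optimally (minimum-total-cost assignment, equivalent to exhaustive
    search); larger components greedily lowest-cost-first.
    """
    # union-find over the bipartite candidate graph
    parent = list(range(n_neurons + n_rois))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for _, ni, ri in cand:
        ra, rb = find(ni), find(n_neurons + ri)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[tuple[float, int, int]]] = {}
    for c in cand:
        comps.setdefault(find(c[1]), []).append(c)

    assigned: list[tuple[int, int]] = []
    for edges in comps.values():
        neurons = sorted({ni for _, ni, _ in edges})
        rois_ = sorted({ri for _, _, ri in edges})
        if len(neurons) <= small and len(rois_) <= small:
            big = 1e12
            mat = np.full((len(neurons), len(rois_)), big)
            for cost, ni, ri in edges:
                mat[neurons.index(ni), rois_.index(ri)] = min(
                    mat[neurons.index(ni), rois_.index(ri)], cost)
            # pad to square so unmatched items stay unmatched at high cost
            rr, cc = linear_sum_assignment(mat)
            for a, b in zip(rr, cc):
                if mat[a, b] < big:
                    assigned.append((neurons[a], rois_[b]))
        else:
            taken_n: set[int] = set()
            taken_r: set[int] = set()
            for cost, ni, ri in sorted(edges):
                if ni in taken_n or ri in taken_r:
                    continue
                taken_n.add(ni)
                taken_r.add(ri)
                assigned.append((ni, ri))
    return assigned


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def register(canonical: CanonicalMap, rois: ROISet,
             user_pairs: pd.DataFrame) -> AssignmentMap:
    """Coarse + fine + automatic assignment in one call."""
    transforms = coarse_align(user_pairs, canonical, rois)
    warp = fine_align(user_pairs, canonical, rois, transforms)
    return auto_assign(canonical, rois, transforms, warp, user_pairs)


def iterate_registration(canonical: CanonicalMap, rois: ROISet,
                         user_pairs: pd.DataFrame,
                         confirm=None, max_rounds: int = 5) -> AssignmentMap:
    """Batch emulation of the confirm -> align -> assign loop.

    ``confirm(assignment) -> DataFrame`` may supply extra confirmed pairs
    after each round (e.g. the high-confidence automatic matches a user
    would accept).  Iterates until the assignment is stable or
    ``max_rounds`` is reached.
    """
    pairs = user_pairs.copy()
    prev: dict[str, str] | None = None
    assignment = None
    for _ in range(max_rounds):
        assignment = register(canonical, rois, pairs)
        current = assignment.as_dict()
        if prev is not None and current == prev:
            break
        prev = current
        if confirm is not None:
            extra = confirm(assignment)
            if extra is not None and len(extra):
                pairs = pd.concat([pairs, extra], ignore_index=True)
                pairs = pairs.drop_duplicates(subset=["roi_id"], keep="first")
                pairs = pairs.drop_duplicates(subset=["neuron_id"], keep="first")
    assert assignment is not None
    return assignment


class CanonicalRegistration(BaseEstimator):
    """Estimator interface for canonical-map registration of one aspect.

    Parameters
    ----------
    canonical : CanonicalMap
        The canonical chart of the imaged aspect.
    min_pairs : int
        Anchors required before a packet gets its own affine transform.

    Attributes
    ----------
    transforms_ : dict mapping packet id (or None) to PacketTransform
    warp_ : WarpField
    assignment_ : AssignmentMap
    """

    def __init__(self, canonical: CanonicalMap | None = None,
                 min_pairs: int = 3):
        self.canonical = canonical
        self.min_pairs = min_pairs

    def fit(self, X: ROISet, y: pd.DataFrame | None = None
            ) -> "CanonicalRegistration":
        """Fit from the ROIs of one view and the confirmed pairs ``y``."""
        if self.canonical is None:
            raise ValueError("a canonical map is required")
        if y is None or not len(y):
            raise ValueError("confirmed (roi_id, neuron_id) pairs are required")
        self.transforms_ = coarse_align(y, self.canonical, X, self.min_pairs)
        self.warp_ = fine_align(y, self.canonical, X, self.transforms_)
        self.assignment_ = auto_assign(self.canonical, X, self.transforms_,
                                       self.warp_, y)
        return self

    def predict(self, neuron_ids: list[str]) -> np.ndarray:
        """Warped image-space positions of the given canonical neurons."""
        pos = _warped_positions(self.canonical, self.transforms_, self.warp_)
        return np.asarray([pos[str(n)] for n in neuron_ids])


def plot_overlay(canonical: CanonicalMap, rois: ROISet,
                 assignment: AssignmentMap, ax=None):
    """Overlay warped canonical positions on ROI centers for inspection."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    centers = _roi_centers(rois)
    pos = _warped_positions(canonical, assignment.transforms,
                            assignment.warp)
    roi_xy = np.asarray(list(centers.values()))
    ax.scatter(roi_xy[:, 0], roi_xy[:, 1], s=25, c="tab:orange",
               label="ROIs")
    can_xy = np.asarray(list(pos.values()))
    ax.scatter(can_xy[:, 0], can_xy[:, 1], marker="x", s=25, c="k",
               label="canonical (warped)")
    for _, row in assignment.pairs.iterrows():
        a = centers[row["roi_id"]]
        b = pos[row["neuron_id"]]
        ax.plot([a[0], b[0]], [a[1], b[1]], lw=0.5, c="gray")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=7)
    ax.invert_yaxis()
    return ax
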